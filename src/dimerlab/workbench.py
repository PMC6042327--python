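"""Config-driven virtual experiment across all four techniques.

A run builds an open reference ensemble and a scenario (open, closed or
mixed) test ensemble of coarse-grained dimers, simulates SAXS, DEER, NMR
relaxation and native-MS observables for both at fixed seeds, analyzes
them with the package's own tools, and evaluates the four cross-technique
signatures of a C-terminally closed homodimer:

1. the inter-domain P(r) peak is more pronounced,
2. EOM selects an ensemble of markedly lower Rg than its pool,
3. the central-domain rotational correlation time is larger,
4. the C-proximal interlabel DEER distance mode is shorter,

each measured for the test scenario against the open reference.  Reports
are deterministic: the same config regenerates byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import confgen, deer, massdeconv, nmr, saxs

DEFAULT_CONFIG = {
    "architecture": "default",
    "scenario": "closed",
    "fraction_closed": 0.5,          # used by scenario == "mixed"
    "seed": 1234,
    "ensemble_size": 30,             # conformers per simulated ensemble
    "pool_size": 60,                 # EOM pool (half open / half closed)
    "eom_pick": 10,
    "saxs": {
        "s_min": 0.05, "s_max": 3.0, "n_s": 120,
        "noise": 0.01, "dmax": 22.0,
        "interdomain_band": [3.5, 7.0],
        "pronounced_ratio": 1.1,
    },
    "deer": {
        "site": 197, "noise_sd": 0.033, "width_nm": 0.25,
        "mode_margin_nm": 0.2,
        "acquisition": {"tau2_us": 8.0},
    },
    "nmr": {
        "nu_n_hz": 60.8e6,
        "nt_tc_ns": 10.5,
        "tpr_tc_open_ns": 9.5,
        "tpr_tc_closed_ns": 12.0,
        "noise_sd": 0.03,
        "tc_margin_ns": 0.5,
    },
    "ms": {
        "monomer_mass_da": 34000.0,
        "adduct_da": 370.0,
        "n_adducts": 4,
        "mz_noise_ppm": 5.0,
    },
}


class StageFailure(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class ExperimentConfig:
    values: dict = field(default_factory=lambda: _deep_copy(DEFAULT_CONFIG))

    def __post_init__(self):
        _check_keys(self.values, DEFAULT_CONFIG, path="config")
        merged = _deep_merge(_deep_copy(DEFAULT_CONFIG), self.values)
        if merged["scenario"] not in ("open", "closed", "mixed"):
            raise ValueError("scenario must be open, closed or mixed")
        if not 0 <= merged["fraction_closed"] <= 1:
            raise ValueError("fraction_closed must be in [0, 1]")
        self.values = merged

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(values=yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def __getitem__(self, key):
        return self.values[key]


def _deep_copy(d):
    return json.loads(json.dumps(d))


def _deep_merge(base: dict, override: dict) -> dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            base[k] = _deep_merge(base[k], v)
        else:
            base[k] = v
    return base


def _check_keys(values: dict, reference: dict, path: str) -> None:
    for k, v in values.items():
        if k not in reference:
            raise ValueError(f"unknown config key {path}.{k}")
        if isinstance(v, dict) and isinstance(reference[k], dict):
            _check_keys(v, reference[k], f"{path}.{k}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_seeds(master: int) -> dict[str, int]:
    names = ("ensemble_ref", "ensemble_test", "pool", "saxs",
             "eom", "deer", "nmr", "ms")
    state = np.random.SeedSequence(master).generate_state(len(names))
    return {n: int(s & 0x7FFF_FFFF) for n, s in zip(names, state)}


def _build_ensemble(arch, n, fraction_closed, seed):
    return confgen.generate_pool(arch, n, fraction_closed, seed)


def _ensemble_curve(pool, s_grid, noise, seed) -> saxs.ScatteringCurve:
    curves = np.array([saxs.debye_intensity(m, s_grid).I
                       for m in pool.conformers])
    mean = curves.mean(axis=0)
    rng = np.random.default_rng(seed)
    sigma = noise * mean
    noisy = mean + sigma * rng.standard_normal(len(mean))
    return saxs.ScatteringCurve(s_grid, noisy, sigma)


def _interdomain_peak_height(pr: saxs.PofR, band) -> float:
    mask = (pr.r >= band[0]) & (pr.r <= band[1])
    norm = np.trapezoid(pr.p, pr.r)
    if norm <= 0 or not mask.any():
        return 0.0
    return float(np.max(pr.p[mask]) / norm)


def _deer_distribution(pool, site_residue, width_nm) -> deer.DistanceDistribution:
    site = confgen.SpinLabelSite(site_residue)
    dists = [confgen.interlabel_distance(m, site) for m in pool.conformers]
    r = deer.default_r_grid()
    values = np.zeros_like(r)
    for d in dists:
        values += np.exp(-0.5 * ((r - d) / width_nm) ** 2)
    return deer.DistanceDistribution.from_values(r, values)


def _main_mode(dist: deer.DistanceDistribution) -> float:
    stats = deer.distribution_stats(dist, prominence=0.1, min_mass=0.05)
    if not stats:
        return float("nan")
    return max(stats, key=lambda m: m["mass"])["mode"]


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def run_virtual_experiment(config: ExperimentConfig,
                           out_dir: Optional[Path] = None) -> dict:
    """Run the full virtual experiment; returns the report dict (also
    written as JSON + text summary into ``out_dir`` when given).

    Any stage failure raises StageFailure naming the stage; results of
    completed stages are retained on the exception as ``partial``.
    """
    cfg = config.values
    seeds = _stage_seeds(cfg["seed"])
    report: dict = {
        "software": {"name": "dimerlab", "version": __version__},
        "config_hash": config.hash(),
        "config": cfg,
        "seeds": seeds,
        "stages": {},
    }
    stage = "confgen"
    try:
        arch = (confgen.sgta_like_architecture()
                if cfg["architecture"] == "default"
                else confgen.DomainArchitecture.from_yaml(cfg["architecture"]))
        frac = {"open": 0.0, "closed": 1.0,
                "mixed": cfg["fraction_closed"]}[cfg["scenario"]]
        ens_ref = _build_ensemble(arch, cfg["ensemble_size"], 0.0,
                                  seeds["ensemble_ref"])
        if cfg["scenario"] == "open":
            ens_test = ens_ref       # identical, so the comparison is null
        else:
            ens_test = _build_ensemble(arch, cfg["ensemble_size"], frac,
                                       seeds["ensemble_test"])
        report["stages"]["confgen"] = {
            "n_conformers": len(ens_ref),
            "rg_ref_mean_nm": round(float(ens_ref.rg.mean()), 4),
            "rg_test_mean_nm": round(float(ens_test.rg.mean()), 4),
        }

        stage = "saxs"
        scfg = cfg["saxs"]
        s_grid = np.linspace(scfg["s_min"], scfg["s_max"], scfg["n_s"])
        curve_ref = _ensemble_curve(ens_ref, s_grid, scfg["noise"], seeds["saxs"])
        curve_test = _ensemble_curve(ens_test, s_grid, scfg["noise"],
                                     seeds["saxs"])
        pr_ref = saxs.ift_pofr(curve_ref, scfg["dmax"])
        pr_test = saxs.ift_pofr(curve_test, scfg["dmax"])
        h_ref = _interdomain_peak_height(pr_ref, scfg["interdomain_band"])
        h_test = _interdomain_peak_height(pr_test, scfg["interdomain_band"])
        g_ref = saxs.guinier_fit(curve_ref)
        g_test = saxs.guinier_fit(curve_test)
        report["stages"]["saxs"] = {
            "rg_guinier_ref_nm": round(g_ref.rg, 4),
            "rg_guinier_test_nm": round(g_test.rg, 4),
            "interdomain_peak_ref": round(h_ref, 6),
            "interdomain_peak_test": round(h_test, 6),
        }

        stage = "eom"
        pool = _build_ensemble(arch, cfg["pool_size"], 0.5, seeds["pool"])
        pool_I = np.array([saxs.debye_intensity(m, s_grid).I
                           for m in pool.conformers])
        fit = saxs.eom_select([I for I in pool_I], curve_test,
                              ensemble_size=cfg["eom_pick"],
                              ga_config={"generations": 60},
                              rng_seed=seeds["eom"], pool_rg=pool.rg)
        rg_pool_mean = float(pool.rg.mean())
        rg_pool_sd = float(pool.rg.std(ddof=1))
        rg_sel_mean = float(fit.rg_selected.mean())
        report["stages"]["eom"] = {
            "chi2": round(fit.chi2, 4),
            "rg_pool_mean_nm": round(rg_pool_mean, 4),
            "rg_pool_sd_nm": round(rg_pool_sd, 4),
            "rg_selected_mean_nm": round(rg_sel_mean, 4),
        }

        stage = "nmr"
        ncfg = cfg["nmr"]
        tc_by_scenario = {
            "open": ncfg["tpr_tc_open_ns"],
            "closed": ncfg["tpr_tc_closed_ns"],
            "mixed": (cfg["fraction_closed"] * ncfg["tpr_tc_closed_ns"]
                      + (1 - cfg["fraction_closed"]) * ncfg["tpr_tc_open_ns"]),
        }
        summaries = {}
        for label, tc in (("ref", ncfg["tpr_tc_open_ns"]),
                          ("test", tc_by_scenario[cfg["scenario"]])):
            data = nmr.simulate_relaxation_dataset(
                {"NT": ncfg["nt_tc_ns"], "TPR": tc}, ncfg["nu_n_hz"],
                noise_sd=ncfg["noise_sd"], rng_seed=seeds["nmr"])
            summaries[label] = nmr.analyze_relaxation_dataset(
                data, ncfg["nu_n_hz"])
        report["stages"]["nmr"] = {
            f"tc_{label}_{dom}_ns": round(sm.tau_c_ns, 3)
            for label, doms in summaries.items()
            for dom, sm in doms.items()
        }

        stage = "deer"
        dcfg = cfg["deer"]
        modes = {}
        for label, ens in (("ref", ens_ref), ("test", ens_test)):
            dist = _deer_distribution(ens, dcfg["site"], dcfg["width_nm"])
            bg = deer.BackgroundModel(k=0.1, modulation_depth=0.3)
            trace = deer.simulate_trace(dist, bg, noise_sd=dcfg["noise_sd"],
                                        acquisition=dcfg["acquisition"],
                                        rng_seed=seeds["deer"])
            result = deer.invert_trace(trace)
            modes[label] = _main_mode(result.distribution)
        report["stages"]["deer"] = {
            "site": dcfg["site"],
            "mode_ref_nm": round(modes["ref"], 3),
            "mode_test_nm": round(modes["test"], 3),
        }

        stage = "ms"
        mcfg = cfg["ms"]
        dimer = 2.0 * mcfg["monomer_mass_da"]
        if cfg["scenario"] == "open":
            species = [(dimer, 1.0)]
        else:
            species = [(dimer + k * mcfg["adduct_da"], 1.0 - 0.15 * k)
                       for k in range(mcfg["n_adducts"] + 1)]
        peaks = massdeconv.simulate_spectrum(species,
                                             mz_noise_ppm=mcfg["mz_noise_ppm"],
                                             rng_seed=seeds["ms"])
        ms_report = massdeconv.analyze_peaklist(
            peaks, monomer_mass_da=mcfg["monomer_mass_da"])
        dimer_found = any(sp.get("oligomer", {}).get("n_mer") == 2
                          for sp in ms_report["species"])
        report["stages"]["ms"] = {
            "n_species": len(ms_report["species"]),
            "dimer_found": bool(dimer_found),
            "adduct_ladder": ms_report["adduct_ladder"],
        }
    except Exception as err:
        failure = StageFailure(f"stage '{stage}' failed: {err}")
        failure.partial = report
        raise failure from err

    # ----- the four closed-state signatures (test vs open reference) -----
    scfg, dcfg, ncfg = cfg["saxs"], cfg["deer"], cfg["nmr"]
    tc_ref = report["stages"]["nmr"]["tc_ref_TPR_ns"]
    tc_test = report["stages"]["nmr"]["tc_test_TPR_ns"]
    signatures = {
        "interdomain_peak_pronounced": {
            "value_ref": h_ref, "value_test": h_test,
            "effect": round(h_test / h_ref, 4) if h_ref > 0 else None,
            "passed": bool(h_ref > 0 and h_test / h_ref > scfg["pronounced_ratio"]),
        },
        "eom_rg_compaction": {
            "value_ref": round(rg_pool_mean, 4),
            "value_test": round(rg_sel_mean, 4),
            "effect": round((rg_pool_mean - rg_sel_mean) / rg_pool_sd, 4),
            "passed": bool(rg_pool_mean - rg_sel_mean > 0.25 * rg_pool_sd),
        },
        "tpr_tumbling_slowed": {
            "value_ref": tc_ref, "value_test": tc_test,
            "effect": round(tc_test - tc_ref, 4),
            "passed": bool(tc_test - tc_ref > ncfg["tc_margin_ns"]),
        },
        "deer_mode_shorter": {
            "value_ref": round(modes["ref"], 4),
            "value_test": round(modes["test"], 4),
            "effect": round(modes["ref"] - modes["test"], 4),
            "passed": bool(modes["ref"] - modes["test"] > dcfg["mode_margin_nm"]),
        },
    }
    report["signatures"] = signatures
    report["all_signatures_passed"] = all(s["passed"]
                                          for s in signatures.values())
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2)


def write_report(report: dict, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(report_json(report))
    (out_dir / "summary.txt").write_text(render_summary(report))
    return path


def render_summary(report: dict) -> str:
    lines = [
        f"dimerlab virtual experiment (config {report['config_hash']})",
        f"scenario: {report['config']['scenario']}",
        "",
        "closed-state signatures (test scenario vs open reference):",
    ]
    for name, sig in report["signatures"].items():
        flag = "PASS" if sig["passed"] else "----"
        lines.append(f"  [{flag}] {name}: ref={sig['value_ref']} "
                     f"test={sig['value_test']} effect={sig['effect']}")
    lines.append("")
    lines.append(f"all four signatures: "
                 f"{'YES' if report['all_signatures_passed'] else 'no'}")
    return "\n".join(lines) + "\n"


def compare_reports(report_a: dict, report_b: dict) -> dict:
    """Per-signature deltas between two runs (test-scenario metric of A
    minus that of B), with the seeds that produced them."""
    if report_a["config"]["architecture"] != report_b["config"]["architecture"]:
        raise ValueError("reports come from different architectures")
    out = {}
    for name in report_a["signatures"]:
        a = report_a["signatures"][name]
        b = report_b["signatures"][name]
        out[name] = {
            "value_a": a["value_test"],
            "value_b": b["value_test"],
            "effect_a": a["effect"],
            "effect_b": b["effect"],
            # oriented the same way as each signature's own effect size,
            # so comparing a closed run against an open run from the same
            # seeds reproduces the closed run's internal deltas
            "delta": (None if a["effect"] is None or b["effect"] is None
                      else round(a["effect"] - b["effect"], 6)),
            "seeds_a": report_a["seeds"],
            "seeds_b": report_b["seeds"],
        }
    return out
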