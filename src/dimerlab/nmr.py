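"""Backbone ¹⁵N relaxation, heteronuclear NOE, chemical-shift perturbation
and chemical-shift-index analysis.

Per-residue longitudinal (T1) and transverse (T2) relaxation times come
from single-exponential fits of peak-intensity decays.  Domain-level
rotational correlation times use the isotropic-tumbling estimate

    τc ≈ (1 / 4π ν_N) · sqrt(6 T1/T2 − 7),

valid in the slow-tumbling regime (6 T1/T2 ≥ 7); ν_N is the ¹⁵N resonance
frequency in Hz and must always be supplied explicitly (relaxation data
from different fields must never be mixed silently).

The default delay schedules are the inversion-recovery and CPMG series
used for the reference measurements on the SGTA constructs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

# reference delay schedules (ms)
T1_DELAYS_MS = (30.8, 61.6, 123.2, 246.4, 369.6, 554.4, 739.2,
                985.5, 1232.0, 1386.0, 1540.0)
T2_DELAYS_MS = (16.96, 33.92, 50.88, 67.84, 84.8, 118.72, 152.64,
                186.56, 220.48, 254.4)

# reference domain ranges (1-based inclusive): N-terminal dimerization
# domain 5-65 and TPR 87-206
DEFAULT_DOMAIN_RANGES = {"NT": (5, 65), "TPR": (87, 206)}

DEFAULT_CSP_WEIGHT_N = 0.14
CSI_CA_THRESHOLD_PPM = 0.7
CSI_CO_THRESHOLD_PPM = 0.5
CSI_WINDOW = 4


class TauCDomainError(ValueError):
    """6·T1/T2 < 7: outside the isotropic estimate's domain."""


class EmptyDomainError(ValueError):
    """No converged fits inside the requested residue range."""


# ---------------------------------------------------------------------------
# relaxation decays
# ---------------------------------------------------------------------------

@dataclass
class RelaxationSeries:
    residue_id: int
    experiment_type: str               # "T1" | "T2"
    delays_ms: np.ndarray
    intensities: np.ndarray
    uncertainties: Optional[np.ndarray] = None

    def __post_init__(self):
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.experiment_type not in ("T1", "T2"):
            raise ValueError("experiment_type must be 'T1' or 'T2'")
        if len(self.delays_ms) < 2:
            raise ValueError("need at least two delays")
        if np.any(np.diff(self.delays_ms) <= 0):
            raise ValueError("delays must be strictly increasing")
        if len(self.intensities) != len(self.delays_ms):
            raise ValueError("intensity/delay length mismatch")


@dataclass
class RateFit:
    residue_id: int
    experiment_type: str
    T: float                           # seconds
    uncertainty: float
    residual: float
    converged: bool


def fit_exponential(series: RelaxationSeries) -> RateFit:
    """Nonlinear least squares of I(t) = I₀ exp(−t/T).

    Non-decaying or pathological data yields ``converged=False`` (never an
    exception); fits with only two points are allowed but flagged by a
    warning.
    """
    t = series.delays_ms * 1e-3        # seconds
    I = series.intensities
    if len(t) == 2:
        warnings.warn("exponential fit with only two points", stacklevel=2)
    sigma = series.uncertainties
    # log-linear initial guess
    if I[0] <= 0 or I[-1] >= I[0]:
        return RateFit(series.residue_id, series.experiment_type,
                       np.nan, np.nan, np.nan, converged=False)
    pos = I > 0
    slope, intercept = np.polyfit(t[pos], np.log(I[pos]), 1)
    if slope >= 0:
        return RateFit(series.residue_id, series.experiment_type,
                       np.nan, np.nan, np.nan, converged=False)
    p0 = (np.exp(intercept), -1.0 / slope)
    try:
        popt, pcov = curve_fit(
            lambda tt, i0, T: i0 * np.exp(-tt / T), t, I, p0=p0,
            sigma=sigma, absolute_sigma=sigma is not None, maxfev=10_000)
    except RuntimeError:
        return RateFit(series.residue_id, series.experiment_type,
                       np.nan, np.nan, np.nan, converged=False)
    i0, T = popt
    if T <= 0 or not np.isfinite(T):
        return RateFit(series.residue_id, series.experiment_type,
                       np.nan, np.nan, np.nan, converged=False)
    resid = I - i0 * np.exp(-t / T)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return RateFit(series.residue_id, series.experiment_type,
                   float(T), err, rms, converged=True)


# ---------------------------------------------------------------------------
# correlation time
# ---------------------------------------------------------------------------

def domain_tc(mean_t1_s: float, mean_t2_s: float, nu_n_hz: float) -> float:
    """Isotropic rotational correlation time in ns:

        τc = (1 / 4π ν_N) · sqrt(6 T1/T2 − 7).
    """
    if nu_n_hz <= 0:
        raise ValueError("nu_N must be positive")
    ratio = 6.0 * mean_t1_s / mean_t2_s - 7.0
    if ratio < 0:
        raise TauCDomainError(
            f"6*T1/T2 = {6.0 * mean_t1_s / mean_t2_s:.3f} < 7; the "
            "isotropic slow-tumbling estimate does not apply")
    return float(np.sqrt(ratio) / (4.0 * np.pi * nu_n_hz) * 1e9)


def t2_for_tc(t1_s: float, tc_ns: float, nu_n_hz: float) -> float:
    """Invert the τc equation: the T2 that yields ``tc_ns`` given T1."""
    if tc_ns < 0:
        raise ValueError("tau_c must be non-negative")
    ratio = (tc_ns * 1e-9 * 4.0 * np.pi * nu_n_hz) ** 2 + 7.0
    return 6.0 * t1_s / ratio


@dataclass
class DomainSummary:
    domain: str
    residue_range: tuple[int, int]
    n: int
    mean_t1_s: float
    mean_t2_s: float
    sd_t1_s: float
    sd_t2_s: float
    tau_c_ns: float
    nu_n_hz: float


def summarize_domain(fits: Sequence[RateFit], domain: str,
                     residue_range: tuple[int, int],
                     nu_n_hz: float) -> DomainSummary:
    """Average converged T1/T2 fits inside an inclusive residue range and
    estimate the domain τc.  ``n`` counts residues contributing both a
    converged T1 and a converged T2."""
    lo, hi = residue_range
    by_type: dict[str, dict[int, RateFit]] = {"T1": {}, "T2": {}}
    for f in fits:
        if f.converged and lo <= f.residue_id <= hi:
            by_type[f.experiment_type][f.residue_id] = f
    common = sorted(set(by_type["T1"]) & set(by_type["T2"]))
    if not common:
        raise EmptyDomainError(f"no converged residues in {domain} {residue_range}")
    t1 = np.array([by_type["T1"][r].T for r in common])
    t2 = np.array([by_type["T2"][r].T for r in common])
    return DomainSummary(
        domain=domain, residue_range=(lo, hi), n=len(common),
        mean_t1_s=float(t1.mean()), mean_t2_s=float(t2.mean()),
        sd_t1_s=float(t1.std(ddof=1)) if len(t1) > 1 else 0.0,
        sd_t2_s=float(t2.std(ddof=1)) if len(t2) > 1 else 0.0,
        tau_c_ns=domain_tc(float(t1.mean()), float(t2.mean()), nu_n_hz),
        nu_n_hz=nu_n_hz)


# ---------------------------------------------------------------------------
# heteronuclear NOE
# ---------------------------------------------------------------------------

def het_noe(equilibrium: dict[int, float] | pd.Series,
            saturated: dict[int, float] | pd.Series) -> pd.DataFrame:
    """Per-residue I_sat/I_eq ratios.

    Residues missing from either table — or with zero/invalid equilibrium
    intensity — are excluded and listed in the ``excluded`` attribute of
    the returned frame (``df.attrs['excluded']``)."""
    eq = pd.Series(equilibrium, dtype=float)
    sat = pd.Series(saturated, dtype=float)
    common = eq.index.intersection(sat.index)
    excluded = sorted(set(eq.index).symmetric_difference(sat.index))
    rows = []
    for res in sorted(common):
        if eq[res] == 0 or not np.isfinite(eq[res]) or not np.isfinite(sat[res]):
            excluded.append(res)
            continue
        rows.append({"residue_id": int(res), "ratio": sat[res] / eq[res]})
    df = pd.DataFrame(rows, columns=["residue_id", "ratio"])
    df.attrs["excluded"] = sorted(excluded)
    return df


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------

def csp(table_a: pd.DataFrame, table_b: pd.DataFrame,
        weight_n: float = DEFAULT_CSP_WEIGHT_N) -> pd.DataFrame:
    """Combined amide chemical-shift perturbation between two states:

        Δδ = sqrt(ΔδH² + (w_N · ΔδN)²),  default w_N = 0.14.

    Tables need columns ``residue_id``, ``dH_ppm``, ``dN_ppm``; only
    residues present in both with finite shifts are compared.
    """
    a = table_a.set_index("residue_id")
    b = table_b.set_index("residue_id")
    common = a.index.intersection(b.index)
    rows = []
    for res in sorted(common):
        dh = a.loc[res, "dH_ppm"] - b.loc[res, "dH_ppm"]
        dn = a.loc[res, "dN_ppm"] - b.loc[res, "dN_ppm"]
        if not (np.isfinite(dh) and np.isfinite(dn)):
            continue
        rows.append({"residue_id": int(res),
                     "delta_ppm": float(np.hypot(dh, weight_n * dn))})
    if not rows:
        raise ValueError("no common residues with complete amide shifts")
    return pd.DataFrame(rows)


def load_random_coil_reference() -> pd.DataFrame:
    """Random-coil Cα/Cβ/CO reference shifts for the 20 standard residues."""
    with resources.files("dimerlab.data").joinpath(
            "random_coil_shifts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def csi(table: pd.DataFrame,
        random_coil_ref: Optional[pd.DataFrame] = None,
        ca_threshold: float = CSI_CA_THRESHOLD_PPM,
        co_threshold: float = CSI_CO_THRESHOLD_PPM,
        window: int = CSI_WINDOW) -> pd.DataFrame:
    """Chemical-shift-index profile: per-residue Cα and CO deviations from
    random coil, with a helix call where a ``window``-residue run has mean
    ΔδCα > ``ca_threshold`` and mean ΔδCO > ``co_threshold``.

    ``table`` columns: residue_id, residue_type (3-letter), ca_ppm, co_ppm
    (either may be NaN).  Residues with missing shifts are reported as
    ``undetermined`` — gaps are preserved, never interpolated.  Unknown
    residue types are flagged and skipped.
    """
    ref = load_random_coil_reference() if random_coil_ref is None else random_coil_ref
    ref_idx = ref.set_index("residue_type")
    rows = []
    for _, row in table.sort_values("residue_id").iterrows():
        rtype = str(row["residue_type"]).upper()
        if rtype not in ref_idx.index:
            warnings.warn(f"unknown residue type {rtype!r} skipped", stacklevel=2)
            continue
        dca = row.get("ca_ppm", np.nan) - ref_idx.loc[rtype, "ca_ppm"]
        dco = row.get("co_ppm", np.nan) - ref_idx.loc[rtype, "co_ppm"]
        rows.append({"residue_id": int(row["residue_id"]),
                     "residue_type": rtype,
                     "d_ca_ppm": float(dca), "d_co_ppm": float(dco)})
    prof = pd.DataFrame(rows)
    calls = np.array(["undetermined"] * len(prof), dtype=object)
    complete = prof["d_ca_ppm"].notna() & prof["d_co_ppm"].notna()
    calls[complete.to_numpy()] = "coil"
    res_ids = prof["residue_id"].to_numpy()
    dca = prof["d_ca_ppm"].to_numpy()
    dco = prof["d_co_ppm"].to_numpy()
    # helix: any contiguous-in-sequence window of `window` residues with
    # both mean deviations above threshold marks all its members helical
    for i in range(len(prof) - window + 1):
        idx = slice(i, i + window)
        if res_ids[i + window - 1] - res_ids[i] != window - 1:
            continue
        if not complete.to_numpy()[idx].all():
            continue
        if (np.nanmean(dca[idx]) > ca_threshold
                and np.nanmean(dco[idx]) > co_threshold):
            calls[idx] = "helix"
    prof["call"] = calls
    return prof


# ---------------------------------------------------------------------------
# synthetic relaxation data
# ---------------------------------------------------------------------------

def simulate_relaxation_dataset(domain_tc_map: dict[str, float],
                                nu_n_hz: float,
                                domain_ranges: Optional[dict] = None,
                                t1_scale_s: float = 1.2,
                                noise_sd: float = 0.0,
                                t1_delays_ms: Sequence[float] = T1_DELAYS_MS,
                                t2_delays_ms: Sequence[float] = T2_DELAYS_MS,
                                rng_seed: Optional[int] = None,
                                i0: float = 100.0) -> list[RelaxationSeries]:
    """Per-residue T1/T2 decay series whose domain averages reproduce the
    requested correlation times exactly (noiselessly): each domain uses
    T1 = ``t1_scale_s`` and the T2 obtained by inverting the τc equation.
    Gaussian noise with sd ``noise_sd``·I₀ is added when requested.
    """
    ranges = DEFAULT_DOMAIN_RANGES if domain_ranges is None else domain_ranges
    rng = np.random.default_rng(rng_seed)
    out: list[RelaxationSeries] = []
    for domain, tc in domain_tc_map.items():
        if tc < 0:
            raise ValueError(f"negative tau_c for domain {domain}")
        lo, hi = ranges[domain]
        t2 = t2_for_tc(t1_scale_s, tc, nu_n_hz)
        for res in range(lo, hi + 1):
            for etype, delays, T in (("T1", t1_delays_ms, t1_scale_s),
                                     ("T2", t2_delays_ms, t2)):
                delays = np.asarray(delays, dtype=float)
                ideal = i0 * np.exp(-delays * 1e-3 / T)
                noisy = ideal + (noise_sd * i0 * rng.standard_normal(len(delays))
                                 if noise_sd > 0 else 0.0)
                out.append(RelaxationSeries(residue_id=res,
                                            experiment_type=etype,
                                            delays_ms=delays,
                                            intensities=noisy))
    return out


def analyze_relaxation_dataset(series: Sequence[RelaxationSeries],
                               nu_n_hz: float,
                               domain_ranges: Optional[dict] = None
                               ) -> dict[str, DomainSummary]:
    """Fit every series and summarize each configured domain."""
    ranges = DEFAULT_DOMAIN_RANGES if domain_ranges is None else domain_ranges
    fits = [fit_exponential(s) for s in series]
    return {d: summarize_domain(fits, d, rng, nu_n_hz)
            for d, rng in ranges.items()}


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_intensity_series(path, experiment_type: str) -> list[RelaxationSeries]:
    """TSV with columns (residue_index, delay_ms, intensity)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for res, grp in df.groupby("residue_index"):
        grp = grp.sort_values("delay_ms")
        out.append(RelaxationSeries(residue_id=int(res),
                                    experiment_type=experiment_type,
                                    delays_ms=grp["delay_ms"].to_numpy(),
                                    intensities=grp["intensity"].to_numpy()))
    return out


def read_shift_table(path) -> pd.DataFrame:
    """TSV with columns (residue_index, residue_type, atom, shift_ppm) —
    the thin column set importable from NMR-STAR exports — pivoted to one
    row per residue with dH_ppm/dN_ppm/ca_ppm/cb_ppm/co_ppm columns."""
    df = pd.read_csv(path, sep="\t")
    atom_map = {"H": "dH_ppm", "HN": "dH_ppm", "N": "dN_ppm",
                "CA": "ca_ppm", "CB": "cb_ppm", "C": "co_ppm", "CO": "co_ppm"}
    df["column"] = df["atom"].map(atom_map)
    df = df.dropna(subset=["column"])
    wide = df.pivot_table(index=["residue_index", "residue_type"],
                          columns="column", values="shift_ppm",
                          aggfunc="first").reset_index()
    wide = wide.rename(columns={"residue_index": "residue_id"})
    return wide
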