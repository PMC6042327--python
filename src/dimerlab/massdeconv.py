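"""Native-MS charge-state deconvolution and repeated-adduct ladders.

Positive-ion electrospray of a non-denatured protein produces, for each
species of neutral mass M, a short series of peaks at m/z = (M + z·m_p)/z
over consecutive charges z.  This module assigns those series, derives
intensity-weighted neutral masses, classifies oligomeric state against a
known monomer mass, and detects ladders of species spaced by an (unknown)
repeated adduct mass — the signature used to infer a small molecule bound
at one-to-four copies per dimer.

Peak lists are centroided (m/z, intensity) tables; raw profile data are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROTON_MASS_DA = 1.00728
DEFAULT_SERIES_TOL_PPM = 50.0          # native-MS appropriate
DEFAULT_LADDER_GRID_DA = (100.0, 1000.0, 1.0)
DEFAULT_LADDER_RESIDUAL_DA = 10.0


@dataclass
class MzPeakList:
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz/intensity length mismatch")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class ChargeSeries:
    peak_indices: np.ndarray           # indices into the MzPeakList
    charges: np.ndarray                # positive ints, descending with m/z
    masses: np.ndarray                 # per-peak derived neutral masses
    intensities: np.ndarray

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())


@dataclass
class SpeciesMass:
    mass_da: float                     # intensity-weighted mean
    sd_da: float
    n_peaks: int


@dataclass
class AdductLadder:
    base_mass_da: float
    increment_da: float
    increment_sd_da: float
    stoichiometries: list[int]         # gap-free from 0 (or 1) upward
    residual_sd_da: float


@dataclass
class OligomerAssignment:
    species_mass_da: float
    monomer_mass_da: float
    n_mer: Optional[int]               # None when unassigned
    mass_error_ppm: Optional[float]
    assigned: bool


# ---------------------------------------------------------------------------
# charge-series assignment
# ---------------------------------------------------------------------------

def _mass_from(mz: float, z: int) -> float:
    return z * (mz - PROTON_MASS_DA)


def assign_charge_series(peaks: MzPeakList,
                         z_range: tuple[int, int] = (2, 40),
                         tol_ppm: float = DEFAULT_SERIES_TOL_PPM
                         ) -> list[ChargeSeries]:
    """Find charge-state series among centroided peaks.

    For every pair of adjacent candidate peaks, the consecutive-charge
    hypothesis M = z·(m₂ − m_p) = (z+1)·(m₁ − m_p) (m₁ < m₂) is tested
    over the charge range; consistent runs are extended peak by peak.
    Series are returned disjoint (greedy by total intensity).  Fewer than
    two consistent peaks yields an empty list, never an exception.
    """
    n = len(peaks)
    if n < 2:
        return []
    series: list[ChargeSeries] = []
    used: set[int] = set()
    # peel series off one at a time: regenerate candidates from the
    # still-unassigned peaks after each acceptance, so one species'
    # assignment cannot strand another's peaks in stale candidates
    while True:
        candidates = _series_candidates(peaks, used, z_range, tol_ppm)
        if not candidates:
            break
        mass, members = max(
            candidates, key=lambda c: sum(peaks.intensity[k] for k in c[1]))
        idx = np.array(sorted(members), dtype=int)
        zs = np.array([members[p] for p in idx], dtype=int)
        masses = np.array([_mass_from(peaks.mz[p], members[p]) for p in idx])
        series.append(ChargeSeries(peak_indices=idx, charges=zs,
                                   masses=masses,
                                   intensities=peaks.intensity[idx]))
        used.update(idx.tolist())
    series.sort(key=lambda s: -s.total_intensity)
    return series


def _series_candidates(peaks: MzPeakList, used: set[int],
                       z_range: tuple[int, int],
                       tol_ppm: float) -> list[tuple[float, dict[int, int]]]:
    """Consecutive-charge series hypotheses over the unassigned peaks."""
    zmin, zmax = z_range
    free = [i for i in range(len(peaks)) if i not in used]
    candidates: list[tuple[float, dict[int, int]]] = []
    for a in range(len(free) - 1):
        for b in range(a + 1, len(free)):
            i, j = free[a], free[b]
            mz_lo, mz_hi = peaks.mz[i], peaks.mz[j]
            denom = mz_hi - mz_lo
            if denom <= 0:
                continue
            # z of the higher-m/z peak implied by consecutive charges
            z = int(round((mz_lo - PROTON_MASS_DA) / denom))
            if z < zmin or z + 1 > zmax:
                continue
            m_hi = _mass_from(mz_hi, z)
            m_lo = _mass_from(mz_lo, z + 1)
            if abs(m_hi - m_lo) > tol_ppm * 1e-6 * m_hi:
                continue
            mass = 0.5 * (m_hi + m_lo)
            members = {i: z + 1, j: z}
            _extend_series(peaks, members, mass, z_range, tol_ppm,
                           exclude=used)
            # guard against charge harmonics (an n-mer explains every
            # second charge of its submultiples): keep only the
            # consecutive charge run containing the seed pair
            z2p = {zz: p for p, zz in members.items()}
            lo_z, hi_z = z, z + 1
            while lo_z - 1 in z2p:
                lo_z -= 1
            while hi_z + 1 in z2p:
                hi_z += 1
            members = {z2p[c]: c for c in range(lo_z, hi_z + 1)}
            candidates.append((mass, members))
    return candidates


def _extend_series(peaks: MzPeakList, members: dict[int, int], mass: float,
                   z_range: tuple[int, int], tol_ppm: float,
                   exclude: Optional[set[int]] = None) -> None:
    """Greedily add peaks matching the series mass at unused charges."""
    zmin, zmax = z_range
    taken_z = set(members.values())
    exclude = exclude or set()
    for z in range(zmin, zmax + 1):
        if z in taken_z:
            continue
        mz_pred = (mass + z * PROTON_MASS_DA) / z
        order = np.argsort(np.abs(peaks.mz - mz_pred))
        for k in order[:3]:
            k = int(k)
            if k in members or k in exclude:
                continue
            if abs(_mass_from(peaks.mz[k], z) - mass) <= tol_ppm * 1e-6 * mass:
                members[k] = z
            break


def deconvolve_mass(series: ChargeSeries) -> SpeciesMass:
    """Intensity-weighted mean neutral mass over the series members; the
    SD is the unweighted spread of the per-peak masses."""
    if len(series.peak_indices) < 2:
        raise ValueError("need at least two peaks to deconvolve")
    w = series.intensities
    mean = float(np.average(series.masses, weights=w))
    sd = float(np.std(series.masses, ddof=1))
    return SpeciesMass(mass_da=mean, sd_da=sd, n_peaks=len(series.masses))


def assign_oligomer(species: SpeciesMass, monomer_mass_da: float,
                    tol_fraction: float = 0.01) -> OligomerAssignment:
    """n-mer call: n = round(M / monomer), assigned iff the residual is
    within ``tol_fraction``·M (default 1%, room for adducts/solvent)."""
    if monomer_mass_da <= 0:
        raise ValueError("monomer mass must be positive")
    M = species.mass_da
    n = max(int(round(M / monomer_mass_da)), 1)
    resid = M - n * monomer_mass_da
    if abs(resid) <= tol_fraction * M:
        return OligomerAssignment(M, monomer_mass_da, n,
                                  mass_error_ppm=1e6 * resid / M,
                                  assigned=True)
    return OligomerAssignment(M, monomer_mass_da, None, None, assigned=False)


# ---------------------------------------------------------------------------
# adduct ladders
# ---------------------------------------------------------------------------

def detect_adduct_ladder(masses: Sequence[SpeciesMass] | Sequence[float],
                         max_stoich: int = 6,
                         grid: tuple[float, float, float] = DEFAULT_LADDER_GRID_DA,
                         residual_threshold_da: float = DEFAULT_LADDER_RESIDUAL_DA
                         ) -> Optional[AdductLadder]:
    """Fit M_i ≈ M₀ + k_i·a over integer stoichiometries k_i by a grid
    search on the increment a, minimizing the residual SD.

    Accepted only when at least three rungs participate, the residual SD
    is below ``residual_threshold_da`` (chosen to keep the false-positive
    rate on unrelated masses below ~5%) and the stoichiometries are
    gap-free from 0 or 1; otherwise returns None.
    """
    vals = np.sort(np.array([m.mass_da if isinstance(m, SpeciesMass) else float(m)
                             for m in masses]))
    if len(vals) < 3:
        return None
    lo, hi, step = grid
    best = None
    base = vals[0]
    for a in np.arange(lo, hi + step / 2, step):
        k = np.round((vals - base) / a).astype(int)
        if k.max() > max_stoich or len(set(k.tolist())) < 3:
            continue
        # joint fit of the offset given integer rungs
        m0 = float(np.mean(vals - k * a))
        resid = vals - (m0 + k * a)
        sd = float(np.std(resid, ddof=1))
        if best is None or sd < best[0]:
            best = (sd, float(a), m0, k.copy())
    if best is None:
        return None
    sd, a, m0, k = best
    if sd > residual_threshold_da:
        return None
    ks = sorted(set(int(x) for x in k))
    start = ks[0]
    if start not in (0, 1) or ks != list(range(start, ks[-1] + 1)):
        return None
    # refine the increment by least squares on the accepted rungs
    kk = k.astype(float)
    denom = np.sum((kk - kk.mean()) ** 2)
    if denom > 0:
        a_fit = float(np.sum((kk - kk.mean()) * (vals - vals.mean())) / denom)
        m0 = float(vals.mean() - a_fit * kk.mean())
        resid = vals - (m0 + kk * a_fit)
        sd_fit = float(np.std(resid, ddof=1))
        a, sd = a_fit, sd_fit
    inc_sd = sd / np.sqrt(max(denom, 1e-300))
    return AdductLadder(base_mass_da=m0, increment_da=a,
                        increment_sd_da=float(inc_sd),
                        stoichiometries=ks, residual_sd_da=sd)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_spectrum(species: Sequence[tuple[float, float]],
                      charge_center: Optional[float] = None,
                      charge_width: float = 2.0,
                      n_charges: int = 5,
                      mz_noise_ppm: float = 0.0,
                      rng_seed: Optional[int] = None) -> MzPeakList:
    """Peaks at (M + z·m_p)/z for a Gaussian-weighted charge envelope.

    ``species`` is a list of (neutral mass Da, abundance).  The envelope
    center defaults to the charge giving m/z ≈ 2500 (a typical native-MS
    regime); intensities are abundance × envelope weight; optional
    ppm-scale Gaussian jitter on m/z.
    """
    rng = np.random.default_rng(rng_seed)
    mz, inten = [], []
    for M, abundance in species:
        if M <= 0:
            raise ValueError("species masses must be positive")
        zc = charge_center if charge_center is not None else max(M / 2500.0, 2.0)
        z_lo = max(int(round(zc)) - n_charges // 2, 1)
        for z in range(z_lo, z_lo + n_charges):
            weight = np.exp(-0.5 * ((z - zc) / charge_width) ** 2)
            m_over_z = (M + z * PROTON_MASS_DA) / z
            if mz_noise_ppm > 0:
                m_over_z *= 1.0 + mz_noise_ppm * 1e-6 * rng.standard_normal()
            mz.append(m_over_z)
            inten.append(abundance * weight)
    return MzPeakList(np.array(mz), np.array(inten))


# ---------------------------------------------------------------------------
# TSV / JSON interfaces
# ---------------------------------------------------------------------------

def read_peaklist(path, metadata: Optional[dict] = None) -> MzPeakList:
    df = pd.read_csv(path, sep="\t")
    return MzPeakList(df["mz"].to_numpy(), df["intensity"].to_numpy(),
                      metadata=metadata or {})


def write_peaklist(peaks: MzPeakList, path) -> None:
    pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity}).to_csv(
        path, sep="\t", index=False)


def analyze_peaklist(peaks: MzPeakList, monomer_mass_da: Optional[float] = None,
                     z_range: tuple[int, int] = (2, 40),
                     tol_ppm: float = DEFAULT_SERIES_TOL_PPM) -> dict:
    """Full report: charge series, species masses, oligomer calls and an
    adduct-ladder scan; JSON-serializable."""
    series = assign_charge_series(peaks, z_range, tol_ppm)
    out: dict = {"n_peaks": len(peaks), "species": []}
    masses = []
    for s in series:
        sp = deconvolve_mass(s)
        masses.append(sp)
        entry = {"mass_da": sp.mass_da, "sd_da": sp.sd_da,
                 "n_peaks": sp.n_peaks,
                 "charges": s.charges.tolist(),
                 "total_intensity": s.total_intensity}
        if monomer_mass_da:
            olig = assign_oligomer(sp, monomer_mass_da)
            entry["oligomer"] = {"n_mer": olig.n_mer,
                                 "assigned": olig.assigned,
                                 "mass_error_ppm": olig.mass_error_ppm}
        out["species"].append(entry)
    ladder = detect_adduct_ladder(masses) if len(masses) >= 3 else None
    out["adduct_ladder"] = (None if ladder is None else {
        "base_mass_da": ladder.base_mass_da,
        "increment_da": ladder.increment_da,
        "increment_sd_da": ladder.increment_sd_da,
        "stoichiometries": ladder.stoichiometries,
        "residual_sd_da": ladder.residual_sd_da})
    return out
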