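"""Occupancy statistics, free-energy profiles, critical nucleus, CNT model.

F(n) = -kT ln P(n), reported in kT units and shifted so its minimum is zero;
the interior maximum of F locates the critical nucleus.  The classical
nucleation theory form combines a bulk term -n kT ln S with a surface term
theta * n^(2/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

BOLTZMANN_KCAL = 0.0019872041  # kcal/mol/K

SMALL_SYSTEM_WARNING = (
    "system contains <= 20 monomers and a low critical nucleus; the continuous "
    "CNT expression cannot be fitted reliably at this size and the fitted "
    "parameters must not be trusted without independent validation")


@dataclass
class FreeEnergyProfile:
    """Free energy over a discrete coordinate (aggregate size or beta count)."""

    coordinate: np.ndarray       # grid values
    counts: np.ndarray           # raw per-point sampling counts (pooled)
    probability: np.ndarray      # normalized; zero where unsampled
    free_energy: np.ndarray      # kT units, min 0; NaN where unsampled
    temperature: float
    subset_free_energies: list = field(default_factory=list)  # fluctuation bands

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)

    def stderr_by_subset(self) -> np.ndarray:
        if not self.subset_free_energies:
            return np.full_like(self.free_energy, np.nan)
        stack = np.vstack(self.subset_free_energies)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanstd(stack, axis=0) / np.sqrt(stack.shape[0])


def _counts_to_profile(coordinate, counts, temperature, subset_counts=None):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no samples: all-zero occupancy")
    p = counts / total
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)
    f = f - np.nanmin(f)
    subs = []
    if subset_counts is not None:
        for sc in subset_counts:
            sc = np.asarray(sc, dtype=float)
            if sc.sum() <= 0:
                continue
            sp = sc / sc.sum()
            with np.errstate(divide="ignore"):
                sf = np.where(sp > 0, -np.log(np.where(sp > 0, sp, 1.0)), np.nan)
            subs.append(sf - np.nanmin(sf))
    return FreeEnergyProfile(coordinate=np.asarray(coordinate), counts=counts,
                             probability=p, free_energy=f, temperature=temperature,
                             subset_free_energies=subs)


# ---------------------------------------------------------------------------
# occupancy estimators
# ---------------------------------------------------------------------------

def _run_size_lists(run):
    """Normalize a run into a sequence of per-frame aggregate-size lists."""
    for entry in run:
        yield entry.sizes if hasattr(entry, "sizes") else list(entry)


def size_probability(runs, n_total: int = 20, weighting: str = "per_aggregate",
                     largest_only: bool = False, n_subsets: int = 1):
    """Normalized occupancy P(n) over aggregate sizes, pooled over runs.

    ``per_aggregate``: each aggregate present in a frame adds one count at
    its size (monomers count at size 1).  ``per_peptide``: each aggregate
    adds n counts.  ``largest_only`` restricts to the largest aggregate per
    frame.  ``n_subsets`` > 1 additionally splits the runs round-robin into
    subsets to report free-energy fluctuation bands.
    """
    if weighting not in ("per_aggregate", "per_peptide"):
        raise ValueError(f"unknown weighting {weighting!r}")
    runs = list(runs)
    if not runs:
        raise ValueError("empty ensemble")
    counts = np.zeros(n_total + 1)
    subset_counts = [np.zeros(n_total + 1) for _ in range(n_subsets)] if n_subsets > 1 else None
    for ri, run in enumerate(runs):
        for sizes in _run_size_lists(run):
            sizes = [max(sizes)] if (largest_only and sizes) else sizes
            for s in sizes:
                w = s if weighting == "per_peptide" else 1.0
                counts[s] += w
                if subset_counts is not None:
                    subset_counts[ri % n_subsets][s] += w
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty ensemble")
    return counts, subset_counts


def free_energy_profile(probability_or_counts, temperature: float = 280.0,
                        coordinate=None, subset_counts=None) -> FreeEnergyProfile:
    """F = -kT ln P (kT units, min-shifted to zero); undefined where P = 0."""
    arr = np.asarray(probability_or_counts, dtype=float)
    if coordinate is None:
        coordinate = np.arange(arr.size)
    return _counts_to_profile(coordinate, arr, temperature, subset_counts)


def size_free_energy(runs, n_total: int = 20, temperature: float = 280.0,
                     weighting: str = "per_aggregate", largest_only: bool = False,
                     n_subsets: int = 3) -> FreeEnergyProfile:
    """Convenience: occupancy + free energy over aggregate size 1..n_total."""
    counts, subs = size_probability(runs, n_total, weighting, largest_only, n_subsets)
    return _counts_to_profile(np.arange(n_total + 1), counts, temperature, subs)


# ---------------------------------------------------------------------------
# critical nucleus
# ---------------------------------------------------------------------------

@dataclass
class CriticalNucleus:
    found: bool
    size: int | None = None              # argmax point estimate
    range: tuple | None = None           # plateau bounds (lo, hi)
    barrier: float | None = None         # F at the maximum, kT
    reason: str = ""


def critical_nucleus(profile: FreeEnergyProfile, tie_tolerance: float = 0.5,
                     coordinate_bounds: tuple | None = None) -> CriticalNucleus:
    """Interior argmax of F over sizes 2..N-1, with flat-plateau extent.

    Coordinates whose F lies within ``tie_tolerance`` of the maximum and are
    contiguous with the argmax are reported as a range (e.g. "between 4 and
    5").  A monotone profile yields a no-nucleus flag.
    """
    coord = profile.coordinate
    f = profile.free_energy
    n_max = int(coord.max())
    lo_b, hi_b = coordinate_bounds or (2, n_max - 1)
    mask = profile.defined & (coord >= lo_b) & (coord <= hi_b)
    if mask.sum() < 2:
        return CriticalNucleus(found=False, reason="too few defined interior points")
    idx = np.where(mask)[0]
    fi = f[idx]
    diffs = np.diff(fi)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        return CriticalNucleus(found=False, reason="monotone profile, no interior maximum")
    k = int(idx[np.argmax(fi)])
    fmax = f[k]
    lo = hi = k
    while lo - 1 >= 0 and mask[lo - 1] and f[lo - 1] >= fmax - tie_tolerance:
        lo -= 1
    while hi + 1 < len(coord) and mask[hi + 1] and f[hi + 1] >= fmax - tie_tolerance:
        hi += 1
    return CriticalNucleus(found=True, size=int(coord[k]),
                           range=(int(coord[lo]), int(coord[hi])),
                           barrier=float(fmax))


def beta_residue_free_energy(beta_counts, temperature: float = 280.0,
                             max_count: int | None = None,
                             bin_width: int = 1) -> FreeEnergyProfile:
    """Free energy over the per-frame total number of beta residues."""
    values = np.asarray(list(beta_counts), dtype=int)
    if values.size == 0:
        raise ValueError("empty ensemble")
    m = max_count if max_count is not None else int(values.max())
    edges = np.arange(0, m + bin_width + 1, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    coord = edges[:-1]
    return _counts_to_profile(coord, counts, temperature)


def first_interior_maximum(profile: FreeEnergyProfile,
                           tie_tolerance: float = 0.5) -> CriticalNucleus:
    """First local interior maximum, scanning the coordinate upward.

    Used for the beta-residue profile, where the critical amount of
    secondary structure is the FIRST maximum, not the global one.
    """
    coord = profile.coordinate
    f = profile.free_energy
    idx = np.where(profile.defined)[0]
    if idx.size < 3:
        return CriticalNucleus(found=False, reason="too few defined points")
    fi = f[idx]
    for j in range(1, len(idx) - 1):
        if fi[j] > fi[j - 1] and fi[j] >= fi[j + 1]:
            lo = hi = j
            while lo - 1 > 0 and fi[lo - 1] >= fi[j] - tie_tolerance:
                lo -= 1
            while hi + 1 < len(idx) - 1 and fi[hi + 1] >= fi[j] - tie_tolerance:
                hi += 1
            return CriticalNucleus(found=True, size=int(coord[idx[j]]),
                                   range=(int(coord[idx[lo]]), int(coord[idx[hi]])),
                                   barrier=float(fi[j]))
    return CriticalNucleus(found=False, reason="no interior maximum (flat or monotone)")


# ---------------------------------------------------------------------------
# classical nucleation theory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNTModel:
    """Bulk + surface free-energy model.

    ``supersaturation`` S is dimensionless; ``theta`` is the surface
    coefficient in kT units (it bundles the interfacial energy and the
    geometric prefactor into a single fit coefficient).
    """

    supersaturation: float
    theta: float
    temperature: float = 280.0

    def __post_init__(self):
        if self.supersaturation <= 0:
            raise ValueError("supersaturation must be positive")
        if self.theta < 0:
            raise ValueError("surface coefficient must be non-negative")

    @property
    def n_star(self) -> float | None:
        """Closed-form stationary point (continuous n), for S > 1."""
        if self.supersaturation <= 1 or self.theta == 0:
            return None
        return (2.0 * self.theta / (3.0 * np.log(self.supersaturation))) ** 3


def cnt_free_energy(n, model: CNTModel) -> np.ndarray:
    """Delta G(n) in kT units: -n ln S + theta n^(2/3)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("aggregate size must be >= 1")
    return -n * np.log(model.supersaturation) + model.theta * n ** (2.0 / 3.0)


@dataclass
class CNTFit:
    model: CNTModel | None
    goodness: float
    degenerate: bool
    warnings: list


def cnt_fit(profile: FreeEnergyProfile, temperature: float | None = None) -> CNTFit:
    """Least-squares fit of (S, theta) to a free-energy profile (kT units).

    A small-system warning is always attached for systems of <= 20 monomers;
    the fit is reported but must never be silently trusted there.
    """
    mask = profile.defined & (profile.coordinate >= 1)
    n = profile.coordinate[mask].astype(float)
    f = profile.free_energy[mask]
    if n.size < 4:
        raise ValueError("need at least 4 defined sizes to fit the CNT form")
    warns = []
    if temperature is None:
        temperature = profile.temperature
    if float(np.ptp(f)) < 1e-9:
        return CNTFit(model=None, goodness=0.0, degenerate=True,
                      warnings=["flat profile: fit degenerate"])

    # fit with a free additive offset since the profile is min-shifted
    def form_off(n, ln_s, theta, c):
        return -n * ln_s + theta * n ** (2.0 / 3.0) + c

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(form_off, n, f, p0=(0.1, 1.0, 0.0), maxfev=20000)
    except RuntimeError:
        return CNTFit(model=None, goodness=0.0, degenerate=True,
                      warnings=["CNT fit did not converge"])
    ln_s, theta, _c = popt
    resid = f - form_off(n, *popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    if int(np.max(profile.coordinate)) <= 20:
        warns.append(SMALL_SYSTEM_WARNING)
    model = CNTModel(supersaturation=float(np.exp(ln_s)), theta=max(float(theta), 0.0),
                     temperature=temperature)
    return CNTFit(model=model, goodness=r2, degenerate=False, warnings=warns)
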