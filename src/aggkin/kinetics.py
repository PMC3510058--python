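"""Kinetic bookkeeping on cluster-partition time series.

Frame-to-frame lineage tracking, classification of association/dissociation
events (monomer addition/loss, oligomer fusion/fragmentation, direct
monomers<->oligomer events), per-size creation/destruction rates, binned
event totals, cumulative sigmoidal size curves, nucleation/reversibility
episodes, energy-trace alignment and (n_hbonds, n_contacts) structure maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

MONOMER_ADDITION = "monomer_addition"
MONOMER_LOSS = "monomer_loss"
FUSION = "fusion"
FRAGMENTATION = "fragmentation"
MONOMERS_TO_OLIGOMER = "monomers_to_oligomer"
OLIGOMER_TO_MONOMERS = "oligomer_to_monomers"

EVENT_TYPES = (MONOMER_ADDITION, MONOMER_LOSS, FUSION, FRAGMENTATION,
               MONOMERS_TO_OLIGOMER, OLIGOMER_TO_MONOMERS)

#: association <-> dissociation mirror under time reversal
MIRROR_TYPE = {
    MONOMER_ADDITION: MONOMER_LOSS,
    MONOMER_LOSS: MONOMER_ADDITION,
    FUSION: FRAGMENTATION,
    FRAGMENTATION: FUSION,
    MONOMERS_TO_OLIGOMER: OLIGOMER_TO_MONOMERS,
    OLIGOMER_TO_MONOMERS: MONOMERS_TO_OLIGOMER,
}

ASSOCIATION_TYPES = (MONOMER_ADDITION, FUSION, MONOMERS_TO_OLIGOMER)
DISSOCIATION_TYPES = (MONOMER_LOSS, FRAGMENTATION, OLIGOMER_TO_MONOMERS)
SINGLE_TYPES = (MONOMER_ADDITION, MONOMER_LOSS)
MULTI_TYPES = (FUSION, FRAGMENTATION, MONOMERS_TO_OLIGOMER, OLIGOMER_TO_MONOMERS)


@dataclass(frozen=True)
class KineticEvent:
    t_start: float
    t_end: float
    type: str
    sizes_before: tuple
    sizes_after: tuple
    participants: frozenset = frozenset()
    compound: bool = False     # part of a decomposed compound transition

    def __post_init__(self):
        if sum(self.sizes_before) != sum(self.sizes_after):
            raise ValueError("event does not conserve mass")

    @property
    def time(self) -> float:
        return self.t_end


# ---------------------------------------------------------------------------
# lineage matching
# ---------------------------------------------------------------------------

@dataclass
class LineageComponent:
    """A connected component of the bipartite shared-peptide graph."""

    groups_before: list      # frozensets at t
    groups_after: list       # frozensets at t + dt

    @property
    def unchanged(self) -> bool:
        return (len(self.groups_before) == 1 and len(self.groups_after) == 1
                and self.groups_before[0] == self.groups_after[0])


def match_clusters(groups_before, groups_after) -> list:
    """Group clusters/monomers at consecutive frames into lineage components.

    Groups (clusters and singleton monomers) are connected when they share a
    peptide; each connected component is one independent transformation.
    """
    before = list(groups_before)
    after = list(groups_after)
    pep_to_b = {}
    for i, g in enumerate(before):
        for p in g:
            pep_to_b[p] = i
    parent = list(range(len(before)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    after_owner = []
    for g in after:
        owners = sorted({pep_to_b[p] for p in g if p in pep_to_b})
        if not owners:
            raise ValueError(f"peptides {set(g)} absent from earlier frame")
        for o in owners[1:]:
            union(owners[0], o)
        after_owner.append(owners[0])

    comp_b: dict = {}
    for i in range(len(before)):
        comp_b.setdefault(find(i), []).append(i)
    comp_a: dict = {}
    for j, o in enumerate(after_owner):
        comp_a.setdefault(find(o), []).append(j)

    out = []
    for root, bids in comp_b.items():
        aids = comp_a.get(root, [])
        out.append(LineageComponent(
            groups_before=[before[i] for i in bids],
            groups_after=[after[j] for j in aids]))
    return out


def lineage_identity(component: LineageComponent) -> dict:
    """Map each after-group to the before-group contributing most peptides.

    Ties broken by the lower minimum peptide index of the before-group.
    """
    out = {}
    for g_after in component.groups_after:
        best = max(component.groups_before,
                   key=lambda g: (len(g & g_after), -min(g)))
        out[g_after] = best
    return out


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def _compose_events(pieces, target_size, t0, t1, participants, compound):
    """Events assembling ``pieces`` (size multiset) into one ``target_size``.

    Monomer additions first (onto the largest piece), then pairwise fusions
    (largest first); an all-monomer composition is a single
    monomers_to_oligomer event.
    """
    pieces = sorted(pieces, reverse=True)
    events = []
    if all(p == 1 for p in pieces):
        # dimer formation is a single-monomer event; >= 3 monomers at once
        # is a direct monomers -> oligomer event
        etype = MONOMER_ADDITION if len(pieces) == 2 else MONOMERS_TO_OLIGOMER
        events.append(KineticEvent(t0, t1, etype, tuple(pieces), (target_size,),
                                   participants, compound))
        return events
    ones = [p for p in pieces if p == 1]
    rest = [p for p in pieces if p > 1]
    size = rest.pop(0)
    for _ in ones:
        events.append(KineticEvent(t0, t1, MONOMER_ADDITION, (size, 1),
                                   (size + 1,), participants, compound or bool(rest) or len(ones) > 1))
        size += 1
    for other in rest:
        events.append(KineticEvent(t0, t1, FUSION, tuple(sorted((size, other), reverse=True)),
                                   (size + other,), participants, True))
        size += other
    if size != target_size:
        raise AssertionError("composition bookkeeping error")
    return events


def _decompose_events(source_size, pieces, t0, t1, participants, compound):
    """Mirror of :func:`_compose_events`: split one cluster into pieces."""
    pieces = sorted(pieces, reverse=True)
    events = []
    if all(p == 1 for p in pieces):
        etype = MONOMER_LOSS if len(pieces) == 2 else OLIGOMER_TO_MONOMERS
        events.append(KineticEvent(t0, t1, etype, (source_size,),
                                   tuple(pieces), participants, compound))
        return events
    ones = [p for p in pieces if p == 1]
    rest = [p for p in pieces if p > 1]
    size = source_size
    for _ in ones:
        events.append(KineticEvent(t0, t1, MONOMER_LOSS, (size,), (size - 1, 1),
                                   participants, compound or bool(rest[1:]) or len(ones) > 1))
        size -= 1
    for other in rest[1:]:
        events.append(KineticEvent(t0, t1, FRAGMENTATION, (size,),
                                   tuple(sorted((size - other, other), reverse=True)),
                                   participants, True))
        size -= other
    if size != rest[0]:
        raise AssertionError("decomposition bookkeeping error")
    return events


def classify_component(component: LineageComponent, t0: float, t1: float) -> list:
    """Kinetic events realizing one lineage component's transformation.

    Simple transformations map directly onto the canonical event types;
    compound ones are decomposed greedily (monomer events first, then
    fusion/fragmentation, then monomers<->oligomers) and flagged, never
    dropped.  Many-to-many components are routed through the merged
    intermediate (all pieces assemble, then split).
    """
    if component.unchanged:
        return []
    sizes_b = sorted((len(g) for g in component.groups_before), reverse=True)
    sizes_a = sorted((len(g) for g in component.groups_after), reverse=True)
    if sizes_b == sizes_a and len(sizes_b) == 1:
        return []  # same single group, membership identical up to relabel
    participants = frozenset().union(*component.groups_before)
    total = sum(sizes_b)
    compound = len(sizes_b) > 2 and len(sizes_a) > 2
    if len(sizes_a) == 1:
        return _compose_events(sizes_b, total, t0, t1, participants,
                               compound=False)
    if len(sizes_b) == 1:
        return _decompose_events(total, sizes_a, t0, t1, participants,
                                 compound=False)
    # many-to-many: assemble then split, flagged as compound
    ev = _compose_events(sizes_b, total, t0, t1, participants, compound=True)
    ev += _decompose_events(total, sizes_a, t0, t1, participants, compound=True)
    for e in ev:
        object.__setattr__(e, "compound", True)
    return ev


def classify_events(partition_before, partition_after,
                    t0: float | None = None, t1: float | None = None) -> list:
    """All kinetic events between two consecutive partitions.

    Accepts :class:`~aggkin.sheet_clustering.ClusterPartition` objects or
    plain lists of groups (iterables of peptide indices).
    """
    gb = partition_before.groups() if hasattr(partition_before, "groups") else \
        [frozenset(g) for g in partition_before]
    ga = partition_after.groups() if hasattr(partition_after, "groups") else \
        [frozenset(g) for g in partition_after]
    if t0 is None:
        t0 = getattr(partition_before, "time", 0.0)
    if t1 is None:
        t1 = getattr(partition_after, "time", t0 + 1.0)
    events = []
    for comp in match_clusters(gb, ga):
        events.extend(classify_component(comp, t0, t1))
    return events


def events_for_timeseries(partitions) -> list:
    """Classify events across an ordered sequence of partitions."""
    parts = list(partitions)
    events = []
    for a, b in zip(parts, parts[1:]):
        events.extend(classify_events(a, b))
    return events


def replay_events(initial_sizes, events, max_size: int | None = None):
    """Replay a size histogram through an event stream.

    Returns the histogram after applying all events; raises if any event is
    inconsistent with the running histogram.
    """
    total = sum(initial_sizes)
    m = max_size or total
    hist = np.zeros(m + 1, dtype=int)
    for s in initial_sizes:
        hist[s] += 1
    for e in events:
        for s in e.sizes_before:
            if hist[s] <= 0:
                raise ValueError(f"replay: no size-{s} aggregate available for {e.type}")
            hist[s] -= 1
        for s in e.sizes_after:
            hist[s] += 1
    return hist


# ---------------------------------------------------------------------------
# rates (per-size creation/destruction fluxes) and totals
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Per-size, per-time-bin event counts and rates.

    Four groups are kept separate: creation/destruction of each size via the
    single-monomer route (``c_mono``/``d_mono``) and via multi-monomer routes
    (``c_multi``/``d_multi``).  ``counts`` arrays have shape
    (n_bins, max_size + 1); ``rates`` divide by the bin width.  The net rate
    of creation of size n combines the four groups.
    """

    bin_edges: np.ndarray
    c_mono: np.ndarray
    d_mono: np.ndarray
    c_multi: np.ndarray
    d_multi: np.ndarray
    bin_width: float

    @property
    def net_counts(self) -> np.ndarray:
        return self.c_mono + self.c_multi - self.d_mono - self.d_multi

    @property
    def net_rates(self) -> np.ndarray:
        return self.net_counts / self.bin_width

    def rate(self, group: str) -> np.ndarray:
        return getattr(self, group) / self.bin_width

    def mass_flux(self) -> np.ndarray:
        """sum_n n * net creation count per bin; zero under mass conservation."""
        sizes = np.arange(self.net_counts.shape[1])
        return (self.net_counts * sizes[None, :]).sum(axis=1)


def _bin_index(t, edges):
    i = int(np.searchsorted(edges, t, side="right") - 1)
    return min(max(i, 0), len(edges) - 2)


def _event_fluxes(e: KineticEvent):
    """Yield (group, size, count) flux contributions of one event."""
    if e.type == MONOMER_ADDITION:
        (n, _one), (m,) = e.sizes_before, e.sizes_after
        yield "c_mono", m, 1
        yield "d_mono", n, 1
        yield "d_mono", 1, 1
    elif e.type == MONOMER_LOSS:
        (m,), sizes_a = e.sizes_before, e.sizes_after
        n = max(sizes_a)
        yield "d_mono", m, 1
        yield "c_mono", n, 1
        yield "c_mono", 1, 1
    elif e.type == FUSION:
        (a, b), (m,) = e.sizes_before, e.sizes_after
        yield "c_multi", m, 1
        yield "d_multi", a, 1
        yield "d_multi", b, 1
    elif e.type == FRAGMENTATION:
        (m,), (a, b) = e.sizes_before, e.sizes_after
        yield "d_multi", m, 1
        yield "c_multi", a, 1
        yield "c_multi", b, 1
    elif e.type == MONOMERS_TO_OLIGOMER:
        k = len(e.sizes_before)
        yield "c_multi", e.sizes_after[0], 1
        yield "d_multi", 1, k
    elif e.type == OLIGOMER_TO_MONOMERS:
        k = len(e.sizes_after)
        yield "d_multi", e.sizes_before[0], 1
        yield "c_multi", 1, k
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {e.type}")


def rate_series(events, bin_width: float, t_start: float | None = None,
                t_end: float | None = None, max_size: int = 20,
                save_interval: float | None = None) -> RateSeries:
    """Bin an event stream into per-size creation/destruction rates."""
    if save_interval is not None and bin_width < save_interval:
        raise ValueError("bin width below the frame save interval")
    events = sorted(events, key=lambda e: e.time)
    if t_start is None:
        t_start = events[0].time if events else 0.0
    if t_end is None:
        t_end = events[-1].time if events else t_start + bin_width
    n_bins = max(1, math.ceil((t_end - t_start) / bin_width - 1e-9))
    edges = t_start + bin_width * np.arange(n_bins + 1)
    shape = (n_bins, max_size + 1)
    arrays = {k: np.zeros(shape) for k in ("c_mono", "d_mono", "c_multi", "d_multi")}
    for e in events:
        bi = _bin_index(e.time, edges)
        for group, size, count in _event_fluxes(e):
            arrays[group][bi, size] += count
    return RateSeries(bin_edges=edges, bin_width=bin_width, **arrays)


@dataclass
class EventTotals:
    """Binned totals of single-monomer vs multi-monomer events.

    Association and dissociation are reported separately; ``m_multi`` splits
    further into fusion/fragmentation vs direct monomers<->oligomer events.
    """

    bin_edges: np.ndarray
    single_assoc: np.ndarray
    single_dissoc: np.ndarray
    fusion: np.ndarray
    fragmentation: np.ndarray
    monomers_to_oligomer: np.ndarray
    oligomer_to_monomers: np.ndarray

    @property
    def m_single(self) -> np.ndarray:
        return self.single_assoc + self.single_dissoc

    @property
    def m_multi(self) -> np.ndarray:
        return (self.fusion + self.fragmentation
                + self.monomers_to_oligomer + self.oligomer_to_monomers)

    @property
    def multi_assoc(self) -> np.ndarray:
        return self.fusion + self.monomers_to_oligomer

    @property
    def multi_dissoc(self) -> np.ndarray:
        return self.fragmentation + self.oligomer_to_monomers


def event_totals(events, bin_width: float, t_start: float | None = None,
                 t_end: float | None = None) -> EventTotals:
    events = sorted(events, key=lambda e: e.time)
    if t_start is None:
        t_start = events[0].time if events else 0.0
    if t_end is None:
        t_end = events[-1].time if events else t_start + bin_width
    n_bins = max(1, math.ceil((t_end - t_start) / bin_width - 1e-9))
    edges = t_start + bin_width * np.arange(n_bins + 1)
    fields = {
        MONOMER_ADDITION: "single_assoc", MONOMER_LOSS: "single_dissoc",
        FUSION: "fusion", FRAGMENTATION: "fragmentation",
        MONOMERS_TO_OLIGOMER: "monomers_to_oligomer",
        OLIGOMER_TO_MONOMERS: "oligomer_to_monomers",
    }
    arrays = {v: np.zeros(n_bins) for v in fields.values()}
    for e in events:
        arrays[fields[e.type]][_bin_index(e.time, edges)] += 1
    return EventTotals(bin_edges=edges, **arrays)


# ---------------------------------------------------------------------------
# cumulative size curves and sigmoid fits
# ---------------------------------------------------------------------------

def cumulative_size_curves(runs, max_size: int = 9):
    """Probability over runs of finding an aggregate of at least size s.

    ``runs``: list of runs; each run is a sequence of per-frame size lists
    (or :class:`ClusterPartition` objects).  Returns ``(times, curves,
    monomer_fraction)`` where ``curves[s]`` is the across-run fraction (or
    0/1 indicator for a single run) at each time point.
    """
    def sizes_of(entry):
        return entry.sizes if hasattr(entry, "sizes") else list(entry)

    def time_of(entry, i):
        return entry.time if hasattr(entry, "time") else float(i)

    norm_runs = [list(run) for run in runs]
    if not norm_runs or not norm_runs[0]:
        raise ValueError("need at least one non-empty run")
    n_frames = min(len(r) for r in norm_runs)
    times = np.array([time_of(norm_runs[0][i], i) for i in range(n_frames)])
    curves = {}
    for s in range(2, max_size + 1):
        mat = np.array([[max(sizes_of(run[i]), default=0) >= s
                         for i in range(n_frames)] for run in norm_runs], dtype=float)
        curves[s] = mat.mean(axis=0)
    mono = np.array([[sizes_of(run[i]).count(1) / sum(sizes_of(run[i]))
                      for i in range(n_frames)] for run in norm_runs])
    return times, curves, mono.mean(axis=0)


def _logistic(t, baseline, amplitude, t0, tau):
    return baseline + amplitude / (1.0 + np.exp(-(t - t0) / tau))


@dataclass
class SigmoidFit:
    ok: bool
    amplitude: float = float("nan")
    baseline: float = float("nan")
    t0: float = float("nan")
    tau: float = float("nan")
    goodness: float = float("nan")
    reason: str = ""

    @property
    def lag_time(self) -> float:
        """Tangent construction: intercept of the max-slope tangent with baseline."""
        return self.t0 - 2.0 * self.tau


def fit_sigmoid(times, values, min_goodness: float = 0.9) -> SigmoidFit:
    """Least-squares logistic fit; non-sigmoidal data is flagged, not fitted."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 10:
        return SigmoidFit(ok=False, reason="too few points")
    span = float(np.ptp(y))
    if span < 1e-12:
        return SigmoidFit(ok=False, reason="constant curve")
    p0 = (float(y[0]), span, float(t[np.argmin(np.abs(y - (y[0] + span / 2)))]),
          float(np.ptp(t)) / 10.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_logistic, t, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return SigmoidFit(ok=False, reason="fit did not converge")
    resid = y - _logistic(t, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_goodness:
        return SigmoidFit(ok=False, goodness=r2, reason="non-sigmoidal data")
    baseline, amplitude, t0, tau = popt
    if amplitude < 0:  # canonicalize the mirrored solution
        baseline, amplitude, tau = baseline + amplitude, -amplitude, -tau
    return SigmoidFit(ok=True, amplitude=amplitude, baseline=baseline,
                      t0=t0, tau=tau, goodness=r2)


# ---------------------------------------------------------------------------
# nucleation / reversibility episodes
# ---------------------------------------------------------------------------

@dataclass
class Episode:
    nucleation_time: float
    reversal_time: float | None = None

    @property
    def reversed(self) -> bool:
        return self.reversal_time is not None


def _sustained_from(flags, times, i, hold_time):
    """True if flags stay set from index i for at least hold_time."""
    t0 = times[i]
    j = i
    while j < len(flags) and flags[j]:
        if times[j] - t0 >= hold_time:
            return True
        j += 1
    return False


def detect_nucleation_and_reversibility(times, largest_sizes, n_star: int = 5,
                                        hold_time: float = 500.0,
                                        dissolve_threshold: int = 2) -> list:
    """Find sustained nucleation episodes and their reversals.

    Nucleation: first time the largest cluster reaches ``n_star`` and stays
    there for ``hold_time``.  Reversal: subsequent sustained drop to
    ``dissolve_threshold`` or below.  Multiple episodes per run supported.
    """
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(largest_sizes)
    above = sizes >= n_star
    below = sizes <= dissolve_threshold
    episodes = []
    i = 0
    n = len(times)
    while i < n:
        while i < n and not (above[i] and _sustained_from(above, times, i, hold_time)):
            i += 1
        if i >= n:
            break
        ep = Episode(nucleation_time=float(times[i]))
        while i < n and not (below[i] and _sustained_from(below, times, i, hold_time)):
            i += 1
        if i < n:
            ep.reversal_time = float(times[i])
        episodes.append(ep)
    return episodes


def reversal_fractions(episode_lists) -> dict:
    """Reversibility statistics over runs: per-episode and per-run fractions."""
    eps = [e for run in episode_lists for e in run]
    runs_with = [run for run in episode_lists if run]
    return {
        "episode_fraction": (sum(e.reversed for e in eps) / len(eps)) if eps else float("nan"),
        "run_fraction": (sum(any(e.reversed for e in run) for run in runs_with)
                         / len(runs_with)) if runs_with else float("nan"),
        "n_episodes": len(eps),
        "n_runs": len(runs_with),
    }


# ---------------------------------------------------------------------------
# energy-trace alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedProfile:
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_traces: int
    excluded: int


def _first_downward_crossing(t, e, threshold):
    below = e <= threshold
    if not below.any():
        return None
    idx = int(np.argmax(below))
    if idx == 0:
        return float(t[0])
    t0, t1 = t[idx - 1], t[idx]
    e0, e1 = e[idx - 1], e[idx]
    if e1 == e0:
        return float(t1)
    return float(t0 + (threshold - e0) * (t1 - t0) / (e1 - e0))


def align_energy_traces(traces, threshold: float = -80.0, window: float = 5000.0,
                        grid_step: float | None = None) -> AlignedProfile:
    """Align energy traces at their first downward threshold crossing.

    ``traces``: iterable of (times, energies) arrays.  Each trace is shifted
    so its crossing sits at t=0, then interpolated onto a common grid over
    [-window, +window] (ps); the mean and standard deviation are returned.
    Traces that never cross are excluded with a warning.
    """
    shifted = []
    excluded = 0
    steps = []
    for t, e in traces:
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=float)
        tc = _first_downward_crossing(t, e, threshold)
        if tc is None:
            warnings.warn("energy trace never crosses the alignment threshold; excluded")
            excluded += 1
            continue
        shifted.append((t - tc, e))
        if len(t) > 1:
            steps.append(np.median(np.diff(t)))
    if not shifted:
        raise ValueError("no trace crosses the alignment threshold")
    if grid_step is None:
        grid_step = float(np.median(steps)) if steps else window / 100.0
    grid = np.arange(-window, window + grid_step / 2, grid_step)
    rows = [np.interp(grid, t, e, left=np.nan, right=np.nan) for t, e in shifted]
    stack = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0)
    return AlignedProfile(grid=grid, mean=mean, sd=sd,
                          n_traces=len(shifted), excluded=excluded)


# ---------------------------------------------------------------------------
# structure maps
# ---------------------------------------------------------------------------

@dataclass
class StructureMaps:
    """Three 2D maps over (n_hbonds, n_contacts) coordinates."""

    hb_edges: np.ndarray
    contact_edges: np.ndarray
    last_visit_time: np.ndarray   # NaN where unvisited
    density: np.ndarray           # sums to 1 over visited bins
    parallel: np.ndarray          # mean parallel fraction, NaN where undefined


def structure_maps(n_hbonds, n_contacts, times, parallel_fracs=None,
                   bin_width: int = 2) -> StructureMaps:
    hb = np.asarray(n_hbonds, dtype=float)
    ct = np.asarray(n_contacts, dtype=float)
    times = np.asarray(times, dtype=float)

    def edges(v):
        lo, hi = np.floor(v.min()), np.floor(v.max()) + 1
        return np.arange(lo, hi + bin_width, bin_width)

    hb_e, ct_e = edges(hb), edges(ct)
    nh, nc = len(hb_e) - 1, len(ct_e) - 1
    count = np.zeros((nh, nc))
    last = np.full((nh, nc), np.nan)
    par_sum = np.zeros((nh, nc))
    par_n = np.zeros((nh, nc))
    hi = np.clip(np.searchsorted(hb_e, hb, side="right") - 1, 0, nh - 1)
    ci = np.clip(np.searchsorted(ct_e, ct, side="right") - 1, 0, nc - 1)
    for k in range(len(hb)):
        count[hi[k], ci[k]] += 1
        cur = last[hi[k], ci[k]]
        last[hi[k], ci[k]] = times[k] if np.isnan(cur) else max(cur, times[k])
        if parallel_fracs is not None and parallel_fracs[k] is not None:
            par_sum[hi[k], ci[k]] += parallel_fracs[k]
            par_n[hi[k], ci[k]] += 1
    density = count / count.sum() if count.sum() else count
    with np.errstate(invalid="ignore"):
        parallel = np.where(par_n > 0, par_sum / np.maximum(par_n, 1), np.nan)
    return StructureMaps(hb_edges=hb_e, contact_edges=ct_e,
                         last_visit_time=last, density=density, parallel=parallel)
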