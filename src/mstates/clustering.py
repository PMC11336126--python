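"""Topographic clustering: GFP peaks, polarity-invariant AAHC, GEV, templates.

The analysis samples scalp topographies at peaks of the Global Field Power
(GFP, the spatial standard deviation of the average-referenced potential),
clusters them with the atomize-and-agglomerate hierarchical clustering
(AAHC) algorithm, and summarizes cluster quality with the Global Explained
Variance (GEV).  Polarity is ignored throughout: a topography and its sign
reverse belong to the same microstate class, so correlations enter as
absolute values and cluster centroids are principal axes rather than plain
means (a mean of sign-ambiguous maps can cancel).

For average-referenced maps, the Pearson spatial correlation between two
maps reduces to the cosine of the angle between them, and

    GFP(t) * Corr(v_t, T) = (v_t . T) / sqrt(C)          (T unit norm)

which makes the GEV contribution of a sample simply ``(v_t . T)^2 / C``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DataQualityError, InvalidArgumentError, UndefinedCorrelationError
from .layout import SensorLayout
from .preproc import EpochSet

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class TemplateSet:
    """k microstate template topographies.

    ``maps`` is (k, n_channels); every row is average-referenced (sums to
    zero across channels) and has unit Euclidean norm.  ``class_labels``
    gives the display label of each row (canonically A-D for k=4).
    """

    maps: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        if maps.ndim != 2:
            raise InvalidArgumentError("maps must be (k, n_channels)")
        if len(self.class_labels) != maps.shape[0]:
            raise InvalidArgumentError("one label per map required")
        if not np.allclose(maps.sum(axis=1), 0.0, atol=1e-8):
            raise InvalidArgumentError("maps must be average-referenced")
        if not np.allclose(np.linalg.norm(maps, axis=1), 1.0, atol=1e-8):
            raise InvalidArgumentError("maps must have unit norm")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def default_labels(k: int) -> tuple[str, ...]:
    """A, B, C, D, then M5, M6, ... for larger k."""
    base = ["A", "B", "C", "D"]
    return tuple(base[i] if i < 4 else f"M{i + 1}" for i in range(k))


def _normalize_map(m: np.ndarray) -> np.ndarray:
    m = m - m.mean()
    n = np.linalg.norm(m)
    if n < _NORM_EPS:
        raise UndefinedCorrelationError("zero-variance map")
    return m / n


def spatial_correlation(a: np.ndarray, b: np.ndarray, polarity_invariant: bool = True) -> float:
    """Pearson correlation between two topographies across channels.

    With ``polarity_invariant`` the absolute value is returned, treating a
    map and its sign reverse as identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("maps must have the same length")
    r = float(_normalize_map(a) @ _normalize_map(b))
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


# ---------------------------------------------------------------------------
# GFP and peak extraction
# ---------------------------------------------------------------------------

@dataclass
class GFPSeries:
    """Per-sample GFP (uV) with the epoch each sample came from."""

    values: np.ndarray  # (n_samples_total,)
    sfreq: float
    epoch_index: np.ndarray  # (n_samples_total,) int


@dataclass
class PeakMaps:
    """Topographies at GFP peaks: (n_peaks, n_channels), average-referenced."""

    maps: np.ndarray
    peak_gfp: np.ndarray
    source: np.ndarray  # (n_peaks, 2): (epoch index, sample-within-epoch)


def compute_gfp(ep: EpochSet) -> GFPSeries:
    """Global Field Power per sample of every kept epoch.

    GFP(t) = sqrt( sum_c (v_c(t) - vbar(t))^2 / C ), i.e. the spatial
    standard deviation; for average-referenced data vbar(t) = 0.
    """
    kept = ep.kept()
    centered = kept - kept.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=1))  # (n_kept, S)
    n_kept, s = gfp.shape
    epoch_index = np.repeat(np.flatnonzero(ep.kept_mask), s)
    return GFPSeries(values=gfp.ravel(), sfreq=ep.sfreq, epoch_index=epoch_index)


def find_gfp_peaks(ep: EpochSet, min_separation: int = 0) -> PeakMaps:
    """Strict local GFP maxima per epoch, with the topographies at them.

    Peaks at epoch edges are excluded.  When two peaks fall within
    ``min_separation`` samples, the one with larger GFP wins.
    """
    kept = ep.kept()
    if kept.shape[0] == 0:
        raise DataQualityError("no kept epochs to extract GFP peaks from")
    centered = kept - kept.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=1))  # (E, S)
    kept_ids = np.flatnonzero(ep.kept_mask)
    maps, gfps, src = [], [], []
    for e in range(gfp.shape[0]):
        g = gfp[e]
        idx = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])) + 1
        if min_separation > 1 and len(idx) > 1:
            order = idx[np.argsort(g[idx])[::-1]]
            chosen: list[int] = []
            for i in order:
                if all(abs(i - j) >= min_separation for j in chosen):
                    chosen.append(i)
            idx = np.sort(np.array(chosen, dtype=int))
        for i in idx:
            maps.append(centered[e, :, i])
            gfps.append(g[i])
            src.append((kept_ids[e], i))
    if not maps:
        raise DataQualityError("no GFP peaks found in any epoch")
    return PeakMaps(
        maps=np.asarray(maps),
        peak_gfp=np.asarray(gfps),
        source=np.asarray(src, dtype=int),
    )


# ---------------------------------------------------------------------------
# GEV
# ---------------------------------------------------------------------------

def compute_gev(
    maps: np.ndarray,
    gfp: np.ndarray,
    templates: TemplateSet,
    labels: np.ndarray,
) -> float:
    """Global Explained Variance of a labeling.

    GEV = sum_t (GFP_t * Corr(v_t, T_label(t)))^2 / sum_t GFP_t^2.
    Zero-variance samples contribute nothing to the numerator.
    """
    maps = np.asarray(maps, dtype=float)
    gfp = np.asarray(gfp, dtype=float)
    labels = np.asarray(labels, dtype=int)
    denom = float(np.sum(gfp**2))
    if denom <= 0:
        raise InvalidArgumentError("GEV undefined: all-zero GFP")
    centered = maps - maps.mean(axis=1, keepdims=True)
    c = maps.shape[1]
    dots = np.einsum("tc,tc->t", centered, templates.maps[labels])
    return float(np.sum(dots**2) / c / denom)


# ---------------------------------------------------------------------------
# AAHC
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    """AAHC output over a range of candidate k.

    ``templates[k]`` / ``assignments[k]`` / ``gev[k]`` hold the template
    set, the per-peak cluster assignment and the GEV recorded when the
    agglomeration reached ``k`` clusters.
    """

    templates: dict[int, TemplateSet]
    assignments: dict[int, np.ndarray]
    gev: dict[int, float]
    degenerate: bool = False

    @property
    def ks(self) -> list[int]:
        return sorted(self.gev)


def _principal_axis(member_maps: np.ndarray) -> np.ndarray:
    """GFP-weighted first principal axis of a set of average-referenced maps.

    Raw (uV) maps are used, so each map enters with weight proportional to
    its norm, i.e. its GFP — the polarity-proof analogue of a mean map.
    """
    a = member_maps
    if a.shape[0] == 1:
        v = a[0]
    else:
        cov = a.T @ a
        vals, vecs = np.linalg.eigh(cov)
        v = vecs[:, -1]
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n < _NORM_EPS:
        raise UndefinedCorrelationError("degenerate cluster centroid")
    v = v / n
    # deterministic sign: positive dot with the highest-GFP member
    ref = a[np.argmax(np.linalg.norm(a, axis=1))]
    if ref @ v < 0:
        v = -v
    return v


def aahc_cluster(peaks: PeakMaps, k_min: int = 2, k_max: int = 8) -> ClusteringResult:
    """Atomize-and-agglomerate hierarchical clustering of GFP-peak maps.

    Every peak map starts as a singleton cluster.  Repeatedly, the cluster
    whose members contribute least explained variance —
    ``sum_t (GFP_t * |Corr(v_t, centroid)|)^2`` — is atomized and each freed
    map is reassigned to the surviving cluster with the highest
    polarity-invariant spatial correlation; affected centroids are then
    recomputed as GFP-weighted first principal axes.  A template set,
    assignment and GEV are recorded at every cluster count from ``k_max``
    down to ``k_min``.

    Tie rules (making the procedure deterministic given input order):
    equal contribution -> dissolve the cluster with fewer members, then the
    lowest index; equal correlation on reassignment -> lowest cluster index.

    Once the agglomeration reaches the recorded range (count <= k_max), each
    level is polished by a polarity-invariant k-means-style refinement
    (reassign every map to its best centroid, recompute principal-axis
    centroids, iterate to a fixed point) before being recorded and before
    descending further.  Pure greedy descent occasionally records a clearly
    suboptimal partition at one level, which corrupts the GEV-gain model
    selection; the refinement only ever increases GEV and leaves
    well-separated solutions untouched.
    """
    maps = np.asarray(peaks.maps, dtype=float)
    n, c = maps.shape
    if not 2 <= k_min <= k_max:
        raise InvalidArgumentError("need 2 <= k_min <= k_max")
    if n < k_max:
        raise InvalidArgumentError(f"need at least k_max={k_max} peak maps, got {n}")

    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1)
    nz = norms > _NORM_EPS
    if not nz.all():
        raise InvalidArgumentError("peak maps must have nonzero variance")
    unit = maps / norms[:, None]

    # Degenerate input: all maps collinear -> a single microstate explains
    # everything; clustering into k >= 2 is meaningless.
    if n > 1 and np.all(np.abs(unit @ unit[0]) > 1 - 1e-9):
        warnings.warn("all peak maps are collinear; returning single-class result")
        t = _principal_axis(maps)
        ts = TemplateSet(maps=t[None, :], class_labels=("A",))
        assign = np.zeros(n, dtype=int)
        return ClusteringResult(
            templates={1: ts}, assignments={1: assign}, gev={1: 1.0}, degenerate=True
        )

    # cluster state
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    centroids: dict[int, np.ndarray] = {i: unit[i] for i in range(n)}
    # contribution of cluster = sum over members of (v . centroid)^2 / C
    contrib: dict[int, float] = {i: float(norms[i] ** 2) / c for i in range(n)}
    denom = float(np.sum(norms**2)) / c  # = sum GFP^2

    def _cluster_contrib(cid: int) -> float:
        m = maps[members[cid]]
        return float(np.sum((m @ centroids[cid]) ** 2)) / c

    out_templates: dict[int, TemplateSet] = {}
    out_assign: dict[int, np.ndarray] = {}
    out_gev: dict[int, float] = {}

    def _snapshot(count: int) -> None:
        order = sorted(members)
        tmap = np.array([centroids[cid] for cid in order])
        assign = np.empty(n, dtype=int)
        for new_idx, cid in enumerate(order):
            assign[members[cid]] = new_idx
        ts = TemplateSet(maps=tmap, class_labels=default_labels(count))
        out_templates[count] = ts
        out_assign[count] = assign
        out_gev[count] = sum(contrib.values()) / denom

    def _refine(max_iter: int = 50) -> None:
        """Polarity-invariant k-means polish of the current partition.

        A cluster left empty by reassignment (possible when two centroids
        collapse onto the same direction) is re-seeded with the currently
        worst-explained map, the standard k-means empty-cluster repair.
        """
        for _ in range(max_iter):
            order = sorted(members)
            cent = np.array([centroids[cid] for cid in order])
            corr = np.abs(unit @ cent.T)
            assign = np.argmax(corr, axis=1)
            empty = [j for j in range(len(order))
                     if not np.any(assign == j)]
            if empty:
                explained = (norms * corr[np.arange(n), assign]) ** 2
                for j in empty:
                    worst = int(np.argmin(explained))
                    assign[worst] = j
                    explained[worst] = np.inf
            new_members = {cid: [] for cid in order}
            for t, a in enumerate(assign):
                new_members[order[a]].append(t)
            if all(new_members[cid] == members[cid] for cid in order):
                break
            for cid in order:
                members[cid] = new_members[cid]
                centroids[cid] = _principal_axis(maps[members[cid]])
                contrib[cid] = _cluster_contrib(cid)

    def _try_split_merge() -> bool:
        """One split-worst / merge-closest escape move; keep it if GEV rises.

        The k-means polish cannot rescue a partition in which one cluster
        holds two distinct topographies while two other centroids coincide
        (the orphaned maps correlate ~0 with every centroid).  Splitting the
        cluster with the most unexplained variance along the principal axis
        of its residuals and re-merging the closest centroid pair restores
        exactly such partitions; the move is accepted only when it strictly
        increases GEV, so the search is a deterministic descent.
        """
        import copy

        if len(members) < 2:
            return False
        saved = (copy.deepcopy(members), dict(centroids), dict(contrib))
        gev0 = sum(contrib.values())
        unexplained = {
            cid: float(np.sum(norms[members[cid]] ** 2)) / c - contrib[cid]
            for cid in members
        }
        s = max(unexplained, key=lambda cid: (unexplained[cid], -cid))
        if len(members[s]) < 2 or unexplained[s] <= 1e-12:
            return False
        t0 = centroids[s]
        mem = maps[members[s]]
        resid = mem - np.outer(mem @ t0, t0)
        if np.max(np.linalg.norm(resid, axis=1)) < _NORM_EPS:
            return False
        r = _principal_axis(resid)
        split_off = [m for m in members[s]
                     if abs(unit[m] @ r) > abs(unit[m] @ t0)]
        if not split_off or len(split_off) == len(members[s]):
            return False
        new_id = max(members) + 1
        members[s] = [m for m in members[s] if m not in split_off]
        members[new_id] = split_off
        for cid in (s, new_id):
            centroids[cid] = _principal_axis(maps[members[cid]])
            contrib[cid] = _cluster_contrib(cid)
        # merge the closest pair of centroids to return to the original count
        order_ = sorted(members)
        best_pair, best_corr = None, -1.0
        for i in range(len(order_)):
            for j in range(i + 1, len(order_)):
                cc = abs(float(centroids[order_[i]] @ centroids[order_[j]]))
                if cc > best_corr:
                    best_corr, best_pair = cc, (order_[i], order_[j])
        i, j = best_pair
        members[i] = sorted(members[i] + members.pop(j))
        del centroids[j], contrib[j]
        centroids[i] = _principal_axis(maps[members[i]])
        contrib[i] = _cluster_contrib(i)
        _refine()
        if sum(contrib.values()) > gev0 + 1e-12:
            return True
        members.clear(); members.update(saved[0])
        centroids.clear(); centroids.update(saved[1])
        contrib.clear(); contrib.update(saved[2])
        return False

    while True:
        count = len(members)
        if k_min <= count <= k_max:
            _refine()
            for _ in range(10):
                if not _try_split_merge():
                    break
            _snapshot(count)
        if count <= k_min:
            break
        # pick the weakest cluster: lowest contribution, then fewest members,
        # then lowest index
        victim = min(members, key=lambda cid: (contrib[cid], len(members[cid]), cid))
        freed = members.pop(victim)
        del centroids[victim], contrib[victim]
        order = sorted(members)
        cent = np.array([centroids[cid] for cid in order])  # (K, C)
        corr = np.abs(unit[freed] @ cent.T)  # (m, K)
        best = np.argmax(corr, axis=1)  # first max = lowest index on ties
        touched = set()
        for f, b in zip(freed, best):
            cid = order[b]
            members[cid].append(f)
            touched.add(cid)
        for cid in touched:
            members[cid].sort()
            centroids[cid] = _principal_axis(maps[members[cid]])
            contrib[cid] = _cluster_contrib(cid)

    return ClusteringResult(templates=out_templates, assignments=out_assign, gev=out_gev)


def select_k(cr: ClusteringResult, gev_gain_threshold: float = 0.01) -> int:
    """Smallest k whose GEV gain to k+1 falls below the threshold.

    Returns the largest available k when the gain never drops below the
    threshold; a single-k result returns that k.
    """
    ks = cr.ks
    if len(ks) == 1:
        return ks[0]
    for k in ks[:-1]:
        if k + 1 in cr.gev and cr.gev[k + 1] - cr.gev[k] < gev_gain_threshold:
            return k
    return ks[-1]


# ---------------------------------------------------------------------------
# Template averaging and canonical ordering
# ---------------------------------------------------------------------------

def canonical_maps(layout: SensorLayout) -> TemplateSet:
    """Built-in idealized A-D topographies on a given layout.

    The four canonical microstate classes are approximated by smooth
    gradients over the scalp: A — right-frontal/left-posterior diagonal;
    B — left-frontal/right-posterior diagonal; C — anterior-posterior
    gradient with occipital extremum; D — fronto-central (vertex) extremum.
    Signs are irrelevant downstream (polarity invariance); the maps only
    anchor a reproducible A-D ordering of data-driven templates.
    """
    x, y, z = layout.positions.T
    raw = np.array([x + y, -x + y, y, z])
    maps = []
    for m in raw:
        maps.append(_normalize_map(m))
    return TemplateSet(maps=np.array(maps), class_labels=("A", "B", "C", "D"))


def match_templates(source: TemplateSet, reference: TemplateSet) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of ``source`` maps onto ``reference``.

    Maximizes total polarity-invariant correlation via bipartite assignment.
    Returns (perm, signs): ``source.maps[perm][i] * signs[i]`` corresponds to
    ``reference.maps[i]`` with positive correlation.
    """
    if source.k != reference.k or source.n_channels != reference.n_channels:
        raise InvalidArgumentError("template sets must share k and channel count")
    corr = source.maps @ reference.maps.T  # (k_src, k_ref); maps unit norm, mean 0
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(reference.k, dtype=int)
    signs = np.empty(reference.k)
    for r, ccol in zip(rows, cols):
        perm[ccol] = r
        signs[ccol] = 1.0 if corr[r, ccol] >= 0 else -1.0
    return perm, signs


def align_and_average_templates(
    individual: list[TemplateSet],
    reference: TemplateSet | None = None,
    layout: SensorLayout | None = None,
) -> TemplateSet:
    """Average per-subject template sets into one group set.

    Each subject's maps are matched to the reference (or, when no reference
    is given, to the running average seeded by the first subject) by the
    assignment maximizing total polarity-invariant correlation; signs are
    aligned before averaging and the result renormalized.  With k=4 and a
    layout, the averaged maps are reordered to the canonical A-D classes by
    matching against :func:`canonical_maps`.
    """
    if not individual:
        raise InvalidArgumentError("need at least one template set")
    k = individual[0].k
    c = individual[0].n_channels
    for ts in individual:
        if ts.k != k or ts.n_channels != c:
            raise InvalidArgumentError("all template sets must share k and channel count")

    if reference is not None:
        ref_maps = reference.maps.copy()
        accum = np.zeros((k, c))
        count = 0
    else:
        ref_maps = individual[0].maps.copy()
        accum = ref_maps.copy()
        count = 1
        individual = individual[1:]

    ref = TemplateSet(maps=ref_maps, class_labels=default_labels(k))
    for ts in individual:
        perm, signs = match_templates(ts, ref)
        accum += signs[:, None] * ts.maps[perm]
        count += 1
        if reference is None:
            avg = np.array([_normalize_map(m) for m in accum])
            ref = TemplateSet(maps=avg, class_labels=default_labels(k))
    mean_maps = np.array([_normalize_map(m) for m in accum])
    result = TemplateSet(maps=mean_maps, class_labels=default_labels(k))

    if k == 4 and layout is not None:
        canon = canonical_maps(layout)
        perm, signs = match_templates(result, canon)
        result = TemplateSet(
            maps=signs[:, None] * result.maps[perm],
            class_labels=("A", "B", "C", "D"),
        )
    return result
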