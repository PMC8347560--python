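"""Positional statistics of G4 motifs in transcript coordinates.

Covers region annotation and per-region counts/densities, the 5'-aligned
relative density profile

    d_i = G_i / T_i * 10^3

(G_i = number of motifs covering 1-based position i, T_i = number of
transcripts long enough to have position i), its region-wide background

    average density = l / L * 10^3

(l = total motif nucleotides in the region class, L = total region
length), distance-to-end statistics, metagene profiles of feature density
around anchor positions, the per-bin forming probability

    p_i = d_i(observed) / d'_i(putative)

downstream of anchor sites, and the Mann-Kendall trend test with tie
correction and continuity-corrected normal approximation.

Coordinates are 0-based half-open internally; profile positions i are
1-based offsets from the alignment point in human-facing output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .scan import G4Motif

__all__ = [
    "TranscriptAnnotation",
    "DensityProfile",
    "AnchorProfile",
    "FormingProbability",
    "MKResult",
    "annotate_region",
    "annotate_all",
    "region_counts_density",
    "relative_density_5p",
    "distance_to_ends",
    "metagene_profile",
    "forming_probability",
    "mann_kendall",
]

REGIONS = ("UTR5", "CDS", "UTR3")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Region boundaries: UTR5 = [0, a), CDS = [a, b), UTR3 = [b, L)."""

    transcript_id: str
    utr5_end: int
    cds_end: int
    length: int

    def __post_init__(self) -> None:
        if not 0 <= self.utr5_end <= self.cds_end <= self.length:
            raise ValueError(
                f"{self.transcript_id}: region boundaries must satisfy "
                f"0 <= utr5_end <= cds_end <= length"
            )

    def region_of(self, position: int) -> str:
        if not 0 <= position < self.length:
            raise ValueError(
                f"position {position} outside transcript "
                f"{self.transcript_id} of length {self.length}"
            )
        if position < self.utr5_end:
            return "UTR5"
        if position < self.cds_end:
            return "CDS"
        return "UTR3"

    def region_interval(self, region: str) -> tuple[int, int]:
        if region == "UTR5":
            return (0, self.utr5_end)
        if region == "CDS":
            return (self.utr5_end, self.cds_end)
        if region == "UTR3":
            return (self.cds_end, self.length)
        raise ValueError(f"unknown region {region!r}")


@dataclass
class DensityProfile:
    """Positional density d_i with numerator G_i, denominator T_i and the
    region-wide occupancy background."""

    positions: np.ndarray  # 1-based offsets from the alignment point
    G: np.ndarray
    T: np.ndarray
    d: np.ndarray  # per-kilobase: G/T * 1e3, NaN where T == 0
    background: float  # l / L * 1e3 over the full region class


@dataclass
class AnchorProfile:
    """Feature density at signed offsets around anchor positions."""

    offsets: np.ndarray  # -flank .. +flank
    density: np.ndarray
    control_density: np.ndarray | None = None
    n_anchors: int = 0

    def binned(self, bin_size: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Mean density per bin of ``bin_size`` offsets (left edges)."""
        n = len(self.offsets) // bin_size * bin_size
        dens = self.density[:n].reshape(-1, bin_size)
        edges = self.offsets[:n:bin_size]
        return edges, np.nanmean(dens, axis=1)


@dataclass
class FormingProbability:
    """Per-bin probability that a putative motif is observed folded."""

    bin_starts: np.ndarray  # offsets downstream of the anchors
    d_obs: np.ndarray
    d_put: np.ndarray
    p: np.ndarray  # d_obs / d_put, NaN where d_put == 0


@dataclass(frozen=True)
class MKResult:
    """Mann-Kendall trend statistic and two-sided p-value."""

    S: float
    varS: float
    z: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# region assignment and densities


def annotate_region(
    motif: G4Motif, annotation: TranscriptAnnotation
) -> tuple[str, bool]:
    """Region label for a motif (by its start), plus a spans-boundary flag."""
    label = annotation.region_of(motif.start)
    end_label = annotation.region_of(motif.end - 1)
    return label, label != end_label


def annotate_all(
    motifs: Sequence[G4Motif],
    annotations: Mapping[str, TranscriptAnnotation],
) -> list[G4Motif]:
    """Return motifs with their region field filled in."""
    from dataclasses import replace

    out = []
    for m in motifs:
        ann = annotations[m.transcript_id]
        label, spans = annotate_region(m, ann)
        flags = m.flags + ("spans-boundary",) if spans else m.flags
        out.append(replace(m, region=label, flags=flags))
    return out


def region_counts_density(
    motifs: Sequence[G4Motif],
    annotations: Mapping[str, TranscriptAnnotation],
) -> dict[str, dict[str, float]]:
    """Per-region motif counts, proportions of the total, and counts per
    kilobase of total region length."""
    counts = {r: 0 for r in REGIONS}
    for m in motifs:
        ann = annotations[m.transcript_id]
        label, _ = annotate_region(m, ann)
        counts[label] += 1
    total = sum(counts.values())
    region_len = {r: 0 for r in REGIONS}
    for ann in annotations.values():
        for r in REGIONS:
            a, b = ann.region_interval(r)
            region_len[r] += b - a
    out: dict[str, dict[str, float]] = {}
    for r in REGIONS:
        out[r] = {
            "count": counts[r],
            "proportion": counts[r] / total if total else 0.0,
            "density_per_kb": (
                counts[r] / region_len[r] * 1e3 if region_len[r] else 0.0
            ),
            "region_length": region_len[r],
        }
    return out


def _occupancy_positions(motif: G4Motif) -> range:
    return range(motif.start, motif.end)


def relative_density_5p(
    motifs: Sequence[G4Motif],
    annotations: Mapping[str, TranscriptAnnotation],
    window: int = 300,
    alignment: str = "5p",
    region: str = "UTR5",
    count_mode: str = "occupancy",
) -> DensityProfile:
    """Relative motif density at each of the first ``window`` positions.

    With ``alignment='5p'`` transcripts are aligned at their 5' ends and
    position i (1-based) is the i-th nucleotide; T_i counts transcripts
    with length >= i.  With ``alignment='start_codon'`` position i is the
    i-th nucleotide upstream of the start codon and T_i counts
    transcripts whose 5'-UTR is at least i nt long.

    ``count_mode='occupancy'`` counts a motif at every position it covers;
    ``count_mode='start'`` counts it only at its start position.  The
    background is the occupancy density l/L * 1e3 over the whole region
    class regardless of the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if count_mode not in ("occupancy", "start"):
        raise ValueError("count_mode must be 'occupancy' or 'start'")

    G = np.zeros(window, dtype=np.int64)
    for m in motifs:
        ann = annotations[m.transcript_id]
        if count_mode == "start":
            span = (m.start, m.start + 1)
        else:
            span = (m.start, m.end)
        for pos in range(*span):
            if alignment == "5p":
                i = pos + 1  # 1-based offset from the 5' end
            elif alignment == "start_codon":
                i = ann.utr5_end - pos  # nt upstream of the start codon
            else:
                raise ValueError(f"unknown alignment {alignment!r}")
            if 1 <= i <= window:
                G[i - 1] += 1

    T = np.zeros(window, dtype=np.int64)
    for ann in annotations.values():
        reach = ann.length if alignment == "5p" else ann.utr5_end
        hi = min(reach, window)
        if hi > 0:
            T[:hi] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(T > 0, G / np.maximum(T, 1) * 1e3, np.nan)

    # Eq-2-style background over the full region class
    l_total = 0
    L_total = 0
    for ann in annotations.values():
        a, b = ann.region_interval(region)
        L_total += b - a
    for m in motifs:
        ann = annotations[m.transcript_id]
        a, b = ann.region_interval(region)
        l_total += max(0, min(m.end, b) - max(m.start, a))
    background = l_total / L_total * 1e3 if L_total else float("nan")

    return DensityProfile(
        positions=np.arange(1, window + 1),
        G=G,
        T=T,
        d=d,
        background=background,
    )


def distance_to_ends(
    motifs: Sequence[G4Motif],
    annotations: Mapping[str, TranscriptAnnotation],
    region: str = "UTR5",
) -> list[tuple[G4Motif, int, int]]:
    """(motif, dist5, dist3) for motifs fully inside the region.

    dist5 is from the region's 5' boundary to the motif start; dist3 from
    the motif end to the region's 3' boundary.  Motifs not contained in
    the region are skipped.
    """
    out = []
    for m in motifs:
        ann = annotations[m.transcript_id]
        a, b = ann.region_interval(region)
        if m.start < a or m.end > b:
            continue
        out.append((m, m.start - a, b - m.end))
    return out


# ---------------------------------------------------------------------------
# metagene profiles


def _coverage_masks(
    feature_intervals: Mapping[str, Sequence[tuple[int, int]]],
    lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    masks = {}
    for tid, ivs in feature_intervals.items():
        mask = np.zeros(lengths[tid], dtype=bool)
        for s, e in ivs:
            mask[max(0, s) : min(lengths[tid], e)] = True
        masks[tid] = mask
    return masks


def metagene_profile(
    anchor_positions: Sequence[tuple[str, int]],
    feature_intervals: Mapping[str, Sequence[tuple[int, int]]],
    lengths: Mapping[str, int],
    flank: int = 200,
    control_regions: Mapping[str, tuple[int, int]] | None = None,
    seed: int | None = None,
) -> AnchorProfile:
    """Feature density at signed offsets around anchor positions.

    density(o) = (# anchors whose position + o is covered by a feature)
               / (# anchors whose position + o lies on the transcript).

    When ``control_regions`` is given (one interval per transcript, e.g.
    the 3'-UTR), an equal number of uniform random control anchors is
    drawn from those intervals with ``seed`` and profiled identically.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    anchors = list(anchor_positions)
    if not anchors:
        raise ValueError("no anchor positions supplied")

    masks = _coverage_masks(feature_intervals, lengths)
    offsets = np.arange(-flank, flank + 1)

    def profile(points: Sequence[tuple[str, int]]) -> np.ndarray:
        covered = np.zeros(len(offsets), dtype=np.int64)
        eligible = np.zeros(len(offsets), dtype=np.int64)
        for tid, pos in points:
            L = lengths[tid]
            mask = masks.get(tid)
            for j, o in enumerate(offsets):
                q = pos + o
                if 0 <= q < L:
                    eligible[j] += 1
                    if mask is not None and mask[q]:
                        covered[j] += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(eligible > 0, covered / np.maximum(eligible, 1), np.nan)

    density = profile(anchors)
    control_density = None
    if control_regions is not None:
        rng = np.random.default_rng(seed)
        tids = sorted(control_regions)
        spans = np.array(
            [control_regions[t][1] - control_regions[t][0] for t in tids]
        )
        if spans.sum() <= 0:
            raise ValueError("control regions are empty")
        weights = spans / spans.sum()
        controls = []
        for _ in anchors:
            k = rng.choice(len(tids), p=weights)
            a, b = control_regions[tids[k]]
            controls.append((tids[k], int(rng.integers(a, b))))
        control_density = profile(controls)

    return AnchorProfile(
        offsets=offsets,
        density=density,
        control_density=control_density,
        n_anchors=len(anchors),
    )


def forming_probability(
    og4s: Sequence[G4Motif],
    putatives: Sequence[G4Motif],
    anchors: Sequence[tuple[str, int]],
    lengths: Mapping[str, int],
    depth: int = 200,
    bin_size: int = 20,
) -> FormingProbability:
    """Probability of a putative motif being folded, per bin downstream.

    For each ``bin_size``-nt bin downstream of the anchors, the occupancy
    density of observed motifs is divided by the occupancy density of
    putative motifs, with identical counting rules, so p is in [0, 1]
    whenever the observed set is a subset of the putative set.  Bins with
    zero putative density are undefined (NaN).
    """
    og4_keys = {m.key for m in og4s}
    put_keys = {m.key for m in putatives}
    if not og4_keys <= put_keys:
        raise ValueError("observed motifs must be a subset of putative motifs")

    def intervals(motifs: Sequence[G4Motif]) -> dict[str, list[tuple[int, int]]]:
        d: dict[str, list[tuple[int, int]]] = {}
        for m in motifs:
            d.setdefault(m.transcript_id, []).append((m.start, m.end))
        return d

    obs_masks = _coverage_masks(intervals(og4s), lengths)
    put_masks = _coverage_masks(intervals(putatives), lengths)

    n_bins = depth // bin_size
    cov_obs = np.zeros(n_bins, dtype=np.int64)
    cov_put = np.zeros(n_bins, dtype=np.int64)
    eligible = np.zeros(n_bins, dtype=np.int64)
    for tid, pos in anchors:
        L = lengths[tid]
        om = obs_masks.get(tid)
        pm = put_masks.get(tid)
        for b in range(n_bins):
            for o in range(b * bin_size, (b + 1) * bin_size):
                q = pos + o + 1  # strictly downstream of the anchor
                if 0 <= q < L:
                    eligible[b] += 1
                    if pm is not None and pm[q]:
                        cov_put[b] += 1
                    if om is not None and om[q]:
                        cov_obs[b] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        d_obs = np.where(eligible > 0, cov_obs / np.maximum(eligible, 1), np.nan)
        d_put = np.where(eligible > 0, cov_put / np.maximum(eligible, 1), np.nan)
        p = np.where(cov_put > 0, cov_obs / np.maximum(cov_put, 1), np.nan)

    if np.all(np.isnan(p)):
        raise ValueError("putative density is zero in every bin")

    return FormingProbability(
        bin_starts=np.arange(n_bins) * bin_size,
        d_obs=d_obs,
        d_put=d_put,
        p=p,
    )


# ---------------------------------------------------------------------------
# Mann-Kendall trend test


def mann_kendall(series: Sequence[float]) -> MKResult:
    """Mann-Kendall trend test.

    S is the sum over ordered pairs of sign(x_j - x_i), j > i.  The
    variance uses the tie correction

        varS = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

    over tie groups of size t, and the test statistic is the
    continuity-corrected normal deviate z = (S -/+ 1)/sqrt(varS) with a
    two-sided p-value.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 4:
        raise ValueError("Mann-Kendall test needs at least 4 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    S = 0.0
    for i in range(n - 1):
        S += np.sign(x[i + 1 :] - x[i]).sum()

    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in tie_counts if t > 1)
    varS = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if S > 0:
        z = (S - 1) / math.sqrt(varS)
    elif S < 0:
        z = (S + 1) / math.sqrt(varS)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return MKResult(S=float(S), varS=varS, z=z, p=min(p, 1.0), n=n)
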