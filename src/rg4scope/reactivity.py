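"""DMS-seq reactivity from reverse-transcription stop counts.

DMS methylates accessible (unpaired) A and C bases; reverse transcription
stalls one nucleotide before a methylated base, so the 5' ends of cDNA
reads, shifted by one, count modification events per position.  Comparing
a DMS-treated library against an untreated control yields a per-position
reactivity theta, defined at A/C positions only: high theta means
accessible, near-zero theta means protected (e.g. inside a folded
G-quadruplex).

The reactivity dialect implemented here is the widely used structure-
probing convention:

1. scale both tracks of a transcript to a common depth (each divided by
   its own total stop count, multiplied by the geometric mean of the two
   totals);
2. ``raw_i = max(0, ln(t'_i + 1) - ln(c'_i + 1))`` at A/C positions;
3. 2-8% normalization: divide by the mean of the raw values ranked
   between the 2nd and 8th percentile from the top;
4. clip to ``[0, cap]`` (default cap 7).

Positions at G/U carry no DMS signal and are left undefined (NaN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RTStopTrack",
    "ReactivityTrack",
    "count_rt_stops",
    "compute_reactivity",
    "compute_reactivity_all",
]

log = logging.getLogger(__name__)


@dataclass
class RTStopTrack:
    """Per-position RT-stop counts for one transcript."""

    transcript_id: str
    counts: np.ndarray  # non-negative integers, one per position

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("RT-stop counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ReactivityTrack:
    """Per-position normalized reactivity; NaN where undefined (G/U)."""

    transcript_id: str
    theta: np.ndarray

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.theta)

    def __len__(self) -> int:
        return len(self.theta)


def count_rt_stops(
    read_5p_positions: Iterable[int], transcript_id: str, length: int
) -> RTStopTrack:
    """Attribute each read's 5' end to the base one position upstream.

    A read whose 5' end maps at position ``p`` reports a stop at ``p - 1``;
    reads at position 0 have no upstream base and are dropped.
    """
    counts = np.zeros(length, dtype=np.int64)
    for p in read_5p_positions:
        if not 0 <= p < length:
            raise ValueError(
                f"read 5' position {p} outside transcript "
                f"{transcript_id!r} of length {length}"
            )
        if p == 0:
            continue
        counts[p - 1] += 1
    return RTStopTrack(transcript_id, counts)


def _ac_mask(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("U", "T")
    return np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    # note: callers use (arr == 'A') | (arr == 'C')


def compute_reactivity(
    treated: RTStopTrack,
    control: RTStopTrack,
    sequence: str,
    cap: float = 7.0,
    norm_window: tuple[float, float] | None = (0.02, 0.08),
    min_defined: int = 10,
) -> ReactivityTrack | None:
    """Reactivity for one transcript; None when the transcript is skipped.

    Skips (with a logged warning) transcripts where either track has zero
    total stops or fewer than ``min_defined`` A/C positions exist.
    ``norm_window=None`` disables the 2-8% normalization step.
    """
    if len(treated) != len(control) or len(treated) != len(sequence):
        raise ValueError("treated, control and sequence lengths differ")
    tid = treated.transcript_id

    chars = _ac_mask(sequence)
    ac = (chars == "A") | (chars == "C")
    if int(ac.sum()) < min_defined:
        log.warning("%s skipped: fewer than %d A/C positions", tid, min_defined)
        return None

    t_total = float(treated.counts.sum())
    c_total = float(control.counts.sum())
    if t_total == 0 or c_total == 0:
        log.warning("%s skipped: a track has zero total stops", tid)
        return None

    # step 1: equal-depth scaling by the geometric mean of the two totals
    gm = math.sqrt(t_total * c_total)
    t_scaled = treated.counts * (gm / t_total)
    c_scaled = control.counts * (gm / c_total)

    # step 2: zero-floored log difference at A/C
    raw = np.log(t_scaled + 1.0) - np.log(c_scaled + 1.0)
    raw = np.maximum(raw, 0.0)

    # step 3: 2-8% normalization over the defined positions
    if norm_window is not None:
        vals = np.sort(raw[ac])[::-1]
        n = len(vals)
        lo = int(math.floor(norm_window[0] * n))
        hi = max(int(math.ceil(norm_window[1] * n)), lo + 1)
        scale = float(vals[lo:hi].mean())
        if scale > 0:
            raw = raw / scale

    # step 4: clip, mask G/U
    theta = np.clip(raw, 0.0, cap)
    theta = np.where(ac, theta, np.nan)
    return ReactivityTrack(tid, theta)


def compute_reactivity_all(
    treated: Mapping[str, RTStopTrack],
    control: Mapping[str, RTStopTrack],
    sequences: Mapping[str, str],
    **kwargs,
) -> dict[str, ReactivityTrack]:
    """Reactivity for every transcript present in both count mappings."""
    out: dict[str, ReactivityTrack] = {}
    for tid in sorted(set(treated) & set(control)):
        if tid not in sequences:
            log.warning("%s skipped: no sequence available", tid)
            continue
        track = compute_reactivity(
            treated[tid], control[tid], sequences[tid], **kwargs
        )
        if track is not None:
            out[tid] = track
    return out
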