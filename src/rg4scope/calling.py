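"""Classify putative G4 motifs as observed (folded) or unfolded.

A folded quadruplex shields its bases from DMS, so the A/C positions
inside a folded motif show depressed reactivity relative to the rest of
the transcript.  The default classifier is a protection ratio: the mean
reactivity inside the motif divided by the transcript-wide mean.  Scores
well below 1 indicate protection; a motif is called observed (OG4) when
its score is at or below ``tau_fold``.

An adapter hook lets callers plug in an external constrained-folding
engine instead; any callable mapping (sequence, per-position constraints,
motifs) to per-motif booleans satisfies the contract.  When no engine is
supplied (or the supplied one raises), the protection-ratio rule is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .reactivity import ReactivityTrack
from .scan import G4Motif

__all__ = [
    "FoldCallParams",
    "FoldingEngine",
    "protection_score",
    "call_og4",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldCallParams:
    """Thresholds for the protection-ratio fold call.

    tau_fold: score at or below which a motif is called observed.
    min_ac: minimum defined A/C positions inside the motif for the
        score to be defined at all.
    epsilon: stabilizer added to the transcript mean in the ratio.
    """

    tau_fold: float = 0.5
    min_ac: int = 1
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.tau_fold < 1:
            raise ValueError("tau_fold must be in (0, 1)")
        if self.min_ac < 0:
            raise ValueError("min_ac must be >= 0")


class FoldingEngine(Protocol):
    """Contract for an external constrained-folding engine."""

    def __call__(
        self,
        sequence: str,
        constraints: np.ndarray,
        motifs: Sequence[G4Motif],
    ) -> Sequence[bool]:
        """Return, per motif, whether a quadruplex forms at the motif."""
        ...


def protection_score(
    motif: G4Motif,
    track: ReactivityTrack,
    params: FoldCallParams = FoldCallParams(),
) -> float | None:
    """Mean in-motif reactivity over the transcript-wide mean.

    Returns None (undefined) when fewer than ``params.min_ac`` defined
    A/C positions fall inside the motif.
    """
    if motif.end > len(track):
        raise ValueError(
            f"motif {motif.key} extends past track of length {len(track)}"
        )
    defined = track.defined_mask()
    inside = defined[motif.start : motif.end]
    if int(inside.sum()) < max(params.min_ac, 1):
        return None
    inside_mean = float(np.nanmean(track.theta[motif.start : motif.end]))
    overall_mean = float(np.nanmean(track.theta)) if defined.any() else 0.0
    return inside_mean / (overall_mean + params.epsilon)


def call_og4(
    motifs: Sequence[G4Motif],
    tracks: Mapping[str, ReactivityTrack],
    params: FoldCallParams = FoldCallParams(),
    engine: FoldingEngine | None = None,
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[G4Motif], list[G4Motif]]:
    """Partition putative motifs into (observed, unfolded).

    Every putative motif lands in exactly one list, so
    ``len(observed) + len(unfolded) == len(motifs)`` always.  Motifs on
    transcripts without a reactivity track, or with no probed A/C inside,
    go to the unfolded list with an explanatory flag.
    """
    observed: list[G4Motif] = []
    unfolded: list[G4Motif] = []

    by_transcript: dict[str, list[G4Motif]] = {}
    for m in motifs:
        by_transcript.setdefault(m.transcript_id, []).append(m)

    for tid in sorted(by_transcript):
        group = by_transcript[tid]
        track = tracks.get(tid)
        if track is None:
            log.warning("%s: no reactivity track; motifs flagged no-data", tid)
            unfolded.extend(
                replace(m, status="unfolded", flags=m.flags + ("no-data",))
                for m in group
            )
            continue

        folded_calls: Sequence[bool] | None = None
        if engine is not None:
            seq = (sequences or {}).get(tid, "")
            try:
                folded_calls = list(engine(seq, track.theta, group))
            except Exception as exc:  # engine unavailable -> fall back
                log.warning(
                    "%s: folding engine failed (%s); using protection score",
                    tid,
                    exc,
                )
                folded_calls = None

        for i, m in enumerate(group):
            if folded_calls is not None:
                folded = bool(folded_calls[i])
                if folded:
                    observed.append(replace(m, status="observed"))
                else:
                    unfolded.append(replace(m, status="unfolded"))
                continue
            score = protection_score(m, track, params)
            if score is None:
                unfolded.append(
                    replace(
                        m, status="unfolded", flags=m.flags + ("no-probed-ac",)
                    )
                )
            elif score <= params.tau_fold:
                observed.append(replace(m, status="observed"))
            else:
                unfolded.append(replace(m, status="unfolded"))

    return observed, unfolded
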