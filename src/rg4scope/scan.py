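"""Canonical RNA G-quadruplex motif scanning.

The canonical motif is four guanine tracts of length >= 3 separated by
three loops of 1-7 nt (``G_x N_{1-7} G_x N_{1-7} G_x N_{1-7} G_x`` with
x >= 3).  The analytic minimum motif length is 4*3 + 3*1 = 15 nt.

Parsing rules
-------------
* A G-tract is a *maximal* run of G: a run longer than 3 contributes its
  full length to the tract, never to a loop, so a loop never begins or
  ends with a G adjacent to a tract.
* Matches are reported leftmost, non-overlapping; when several parses
  start at the same position the one ending earliest wins.
* The quartet number of a motif is the minimum of its four tract lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "G4Motif",
    "MIN_MOTIF_LEN",
    "scan_g4",
    "loop_labels",
    "derive_ug4",
    "summarize_motifs",
]

MIN_MOTIF_LEN = 15

_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class G4Motif:
    """One canonical G-quadruplex motif occurrence on a transcript.

    Coordinates are 0-based, half-open, in transcript space.
    """

    transcript_id: str
    start: int
    end: int
    sequence: str
    tract_lengths: tuple[int, int, int, int]
    loop_lengths: tuple[int, int, int]
    region: str = "NA"
    status: str = "putative"
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def quartets(self) -> int:
        return min(self.tract_lengths)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.start, self.end)

    def __post_init__(self) -> None:
        if self.end - self.start != sum(self.tract_lengths) + sum(self.loop_lengths):
            raise ValueError("motif span does not equal tracts + loops")
        if min(self.tract_lengths) < 3:
            raise ValueError("every G-tract must be >= 3 nt")
        if any(not 1 <= l <= 7 for l in self.loop_lengths):
            raise ValueError("loop lengths must be in [1, 7]")
        if self.end - self.start < MIN_MOTIF_LEN:
            raise ValueError("motif shorter than the 15 nt analytic minimum")


def _normalize(sequence: str) -> str:
    """Uppercase, map U->T, reject non-IUPAC characters with position."""
    seq = sequence.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in _IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
    return seq


def _g_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal G-runs of length >= min_len as (start, end) pairs."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scan_g4(
    sequence: str,
    transcript_id: str = "",
    report_overlaps: bool = False,
) -> list[G4Motif]:
    """Find canonical G4 motifs in a sequence.

    Returns leftmost non-overlapping matches sorted by start, with
    ``status='putative'``.  With ``report_overlaps=True`` every candidate
    match (one minimal parse per eligible first tract) is returned
    instead, including mutually overlapping ones.
    """
    seq = _normalize(sequence)
    runs = _g_runs(seq)
    motifs: list[G4Motif] = []
    cursor = 0  # first position not yet consumed by an accepted motif
    for idx in range(len(runs) - 3):
        start = runs[idx][0]
        if not report_overlaps and start < cursor:
            continue
        # greedy: chain the nearest following tracts; this yields the
        # earliest-ending parse for this start
        tracts = [runs[idx]]
        ok = True
        for k in range(1, 4):
            nxt = runs[idx + k]
            gap = nxt[0] - tracts[-1][1]
            if not 1 <= gap <= 7:
                ok = False
                break
            tracts.append(nxt)
        if not ok:
            continue
        end = tracts[-1][1]
        motifs.append(
            G4Motif(
                transcript_id=transcript_id,
                start=start,
                end=end,
                sequence=seq[start:end],
                tract_lengths=tuple(t[1] - t[0] for t in tracts),
                loop_lengths=tuple(
                    tracts[k + 1][0] - tracts[k][1] for k in range(3)
                ),
            )
        )
        if not report_overlaps:
            cursor = end
    return motifs


def loop_labels(motif: G4Motif) -> list[str]:
    """Loop composition labels ``Loop_<k>_<len>`` for the three loops."""
    return [f"Loop_{k + 1}_{l}" for k, l in enumerate(motif.loop_lengths)]


def derive_ug4(
    putative: Sequence[G4Motif], observed: Sequence[G4Motif]
) -> list[G4Motif]:
    """Unfolded set = putative minus observed, by (transcript, start, end).

    Raises ``ValueError`` if an observed motif is absent from the
    putative list (inconsistent inputs).
    """
    putative_keys = {m.key for m in putative}
    for m in observed:
        if m.key not in putative_keys:
            raise ValueError(
                f"observed motif {m.key} not present in the putative set"
            )
    observed_keys = {m.key for m in observed}
    return [
        replace(m, status="unfolded")
        for m in putative
        if m.key not in observed_keys
    ]


def summarize_motifs(motifs: Iterable[G4Motif]) -> dict:
    """Summary table: length/quartet histograms, loop composition,
    fraction with total loop < 10 nt and with all loops <= 3 nt."""
    motifs = list(motifs)
    length_hist: dict[int, int] = {}
    quartet_hist: dict[int, int] = {}
    loop_counts: dict[str, int] = {}
    n_total_loop_lt10 = 0
    n_all_loops_le3 = 0
    for m in motifs:
        length_hist[m.length] = length_hist.get(m.length, 0) + 1
        quartet_hist[m.quartets] = quartet_hist.get(m.quartets, 0) + 1
        for lab in loop_labels(m):
            loop_counts[lab] = loop_counts.get(lab, 0) + 1
        if sum(m.loop_lengths) < 10:
            n_total_loop_lt10 += 1
        if all(l <= 3 for l in m.loop_lengths):
            n_all_loops_le3 += 1
    n = len(motifs)
    return {
        "n_motifs": n,
        "length_hist": dict(sorted(length_hist.items())),
        "quartet_hist": dict(sorted(quartet_hist.items())),
        "loop_composition": dict(sorted(loop_counts.items())),
        "frac_total_loop_lt10": n_total_loop_lt10 / n if n else 0.0,
        "frac_all_loops_le3": n_all_loops_le3 / n if n else 0.0,
    }
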