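"""Synthetic transcriptome with planted G4 motifs and DMS-seq counts.

Every downstream stage of the pipeline is testable against this
generator's ground truth: transcripts with a 5'-UTR/CDS/3'-UTR structure,
canonical G4 motifs planted at known coordinates with known folded /
unfolded status, Poisson RT-stop counts whose DMS signal at A/C positions
is attenuated inside folded motifs, a log-normal expression table with a
planted group effect, and miRNA-target / poly(A) anchor tracks with
planted enrichment or depletion around the motifs.

The generative model for the probing data is deliberately simple so that
its moments are closed-form: control stops are Poisson(lambda_bg)
everywhere; treated stops at an A/C position are
Poisson(lambda_bg + lambda_dms * a) with accessibility a = protection
inside folded planted motifs and a = 1 elsewhere; treated stops at G/T
positions are Poisson(lambda_bg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reactivity import RTStopTrack
from .scan import G4Motif, scan_g4
from .profiling import TranscriptAnnotation

__all__ = [
    "SyntheticConfig",
    "PlantedMotif",
    "GroundTruth",
    "generate_transcriptome",
    "simulate_rtstops",
    "simulate_expression",
    "simulate_anchor_sites",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Length ranges are inclusive (min, max) in nt; the CDS range must
    contain a multiple of 3.  ``n_g4_per_region`` gives planted motif
    counts per transcript for (UTR5, CDS, UTR3).
    """

    n_transcripts: int = 100
    utr5_len: tuple[int, int] = (150, 300)
    cds_len: tuple[int, int] = (300, 900)
    utr3_len: tuple[int, int] = (300, 800)
    gc_background: float = 0.45
    n_g4_per_region: tuple[int, int, int] = (1, 0, 1)
    frac_folded: float = 0.5
    lambda_bg: float = 1.0
    lambda_dms: float = 20.0
    protection: float = 0.1
    expr_mu: float = 3.0
    expr_sigma: float = 1.0
    expr_effect: float = 2.0
    # anchor-track knobs
    n_mirna_per_transcript: int = 3
    mirna_site_len: int = 7
    mirna_enrichment: float = 0.6
    mirna_window: int = 50
    n_polya_per_transcript: int = 1
    polya_exclusion: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("utr5_len", "cds_len", "utr3_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        lo, hi = self.cds_len
        if not any(x % 3 == 0 for x in range(lo, hi + 1)):
            raise ValueError("cds_len range contains no multiple of 3")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0, 1)")
        if not 0 <= self.frac_folded <= 1:
            raise ValueError("frac_folded must be in [0, 1]")
        if self.lambda_dms != 0 and self.lambda_dms <= self.lambda_bg:
            # lambda_dms == 0 is the no-treatment limit; otherwise the
            # DMS signal must rise above background to be recoverable
            raise ValueError("lambda_dms must exceed lambda_bg (or be 0)")
        if not 0 <= self.protection < 1:
            raise ValueError("protection must be in [0, 1)")


@dataclass(frozen=True)
class PlantedMotif:
    transcript_id: str
    start: int
    end: int
    region: str
    folded: bool
    planted: bool = True  # False for motifs arising by chance and reconciled in

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.start, self.end)


@dataclass
class GroundTruth:
    motifs: list[PlantedMotif] = field(default_factory=list)
    expression_group: dict[str, str] = field(default_factory=dict)

    def motifs_of(self, transcript_id: str) -> list[PlantedMotif]:
        return [m for m in self.motifs if m.transcript_id == transcript_id]


_REGIONS = ("UTR5", "CDS", "UTR3")


# loop-length distribution matching the reported composition of in-cell
# G4s: ~57% of motifs have all three loops <= 3 nt, ~90% total loop < 10 nt
_LOOP_LEN_P = np.array([0.40, 0.25, 0.18, 0.07, 0.04, 0.03, 0.03])


def _random_motif(rng: np.random.Generator) -> str:
    """A canonical motif: 3-G tracts, loops of 1-7 nt starting with A or C.

    Loops carry no G so the planted parse is unambiguous; each loop
    starts with an A or C so every motif has DMS-probeable positions.
    """
    parts = []
    for k in range(4):
        parts.append("GGG")
        if k < 3:
            loop_len = int(rng.choice(7, p=_LOOP_LEN_P)) + 1
            loop = [str(rng.choice(["A", "C"]))]
            loop += [str(rng.choice(["A", "C", "T"])) for _ in range(loop_len - 1)]
            parts.append("".join(loop))
    return "".join(parts)


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _place_motifs(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    motif_seqs: Sequence[str],
    occupied: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Non-overlapping slots (with 1-nt non-G margins) inside a region."""
    placements = []
    for seq in motif_seqs:
        need = len(seq)
        if region_end - region_start < need + 2:
            raise ValueError(
                f"region [{region_start}, {region_end}) too short for a "
                f"{need}-nt motif with margins; widen the length ranges "
                f"or reduce n_g4_per_region"
            )
        for _ in range(500):
            s = int(rng.integers(region_start + 1, region_end - need))
            e = s + need
            if all(e + 1 <= a or s - 1 >= b for a, b in occupied):
                placements.append((s, e))
                occupied.append((s, e))
                break
        else:
            raise ValueError(
                "could not place all requested motifs without overlap; "
                "reduce n_g4_per_region or widen the length ranges"
            )
    return placements


def generate_transcriptome(
    cfg: SyntheticConfig,
) -> tuple[dict[str, str], dict[str, TranscriptAnnotation], GroundTruth]:
    """Sequences, region annotations and reconciled ground truth.

    Background sequence is rejection-sampled so that no chance canonical
    motif appears within 30 nt of a planted one; the assembled sequence
    is then re-scanned and the truth reconciled to the actual scan
    result (chance motifs far from planted ones are recorded as
    unplanted, unfolded putatives).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    sequences: dict[str, str] = {}
    annotations: dict[str, TranscriptAnnotation] = {}
    truth = GroundTruth()

    for t in range(cfg.n_transcripts):
        tid = f"TX{t:05d}"
        u5 = int(rng.integers(cfg.utr5_len[0], cfg.utr5_len[1] + 1))
        cds_lo, cds_hi = cfg.cds_len
        cds_choices = [x for x in range(cds_lo, cds_hi + 1) if x % 3 == 0]
        cds = int(cds_choices[rng.integers(0, len(cds_choices))])
        u3 = int(rng.integers(cfg.utr3_len[0], cfg.utr3_len[1] + 1))
        L = u5 + cds + u3
        ann = TranscriptAnnotation(tid, u5, u5 + cds, L)

        bounds = {"UTR5": (0, u5), "CDS": (u5, u5 + cds), "UTR3": (u5 + cds, L)}
        occupied: list[tuple[int, int]] = []
        planted: list[PlantedMotif] = []
        motif_seq_at: dict[int, str] = {}
        for region, n_motifs in zip(_REGIONS, cfg.n_g4_per_region):
            seqs = [_random_motif(rng) for _ in range(n_motifs)]
            a, b = bounds[region]
            for (s, e), mseq in zip(
                _place_motifs(rng, a, b, seqs, occupied), seqs
            ):
                folded = bool(rng.random() < cfg.frac_folded)
                planted.append(PlantedMotif(tid, s, e, region, folded))
                motif_seq_at[s] = mseq

        planted_keys = {(m.start, m.end) for m in planted}
        seq_str = ""
        for _ in range(100):
            chars = _background(rng, L, cfg.gc_background)
            for m in planted:
                chars[m.start : m.end] = list(motif_seq_at[m.start])
                # non-G margins so the planted tracts stay maximal runs
                if m.start > 0 and chars[m.start - 1] == "G":
                    chars[m.start - 1] = str(rng.choice(["A", "C", "T"]))
                if m.end < L and chars[m.end] == "G":
                    chars[m.end] = str(rng.choice(["A", "C", "T"]))
            candidate = "".join(chars)
            found = scan_g4(candidate, tid)
            found_keys = {(f.start, f.end) for f in found}
            if not planted_keys <= found_keys:
                continue  # a chance G-run merged into a planted motif
            stray_near = any(
                (f.start, f.end) not in planted_keys
                and any(
                    f.start < m.end + 30 and m.start - 30 < f.end
                    for m in planted
                )
                for f in found
            )
            if not stray_near:
                seq_str = candidate
                break
        if not seq_str:
            raise ValueError(
                f"{tid}: could not sample a background free of chance "
                f"motifs near planted ones; lower gc_background"
            )

        # reconcile truth with the actual scan result
        by_key = {(m.start, m.end): m for m in planted}
        for f in scan_g4(seq_str, tid):
            key = (f.start, f.end)
            if key in by_key:
                truth.motifs.append(by_key[key])
            else:
                region_label = ann.region_of(f.start)
                truth.motifs.append(
                    PlantedMotif(tid, f.start, f.end, region_label, False, False)
                )

        sequences[tid] = seq_str
        annotations[tid] = ann

    for tid in sequences:
        has_folded_utr3 = any(
            m.folded and m.region == "UTR3" for m in truth.motifs_of(tid)
        )
        truth.expression_group[tid] = "og4_utr3" if has_folded_utr3 else "other"

    return sequences, annotations, truth


def simulate_rtstops(
    sequences: dict[str, str],
    truth: GroundTruth,
    cfg: SyntheticConfig,
) -> tuple[dict[str, RTStopTrack], dict[str, RTStopTrack]]:
    """Poisson treated/control RT-stop tracks per transcript."""
    rng = np.random.default_rng([cfg.seed, 1])
    treated: dict[str, RTStopTrack] = {}
    control: dict[str, RTStopTrack] = {}
    for tid in sorted(sequences):
        seq = sequences[tid]
        L = len(seq)
        chars = np.array(list(seq))
        ac = (chars == "A") | (chars == "C")
        access = np.ones(L)
        for m in truth.motifs_of(tid):
            if m.folded:
                access[m.start : m.end] = cfg.protection
        lam_treated = np.where(
            ac, cfg.lambda_bg + cfg.lambda_dms * access, cfg.lambda_bg
        )
        treated[tid] = RTStopTrack(tid, rng.poisson(lam_treated))
        control[tid] = RTStopTrack(tid, rng.poisson(np.full(L, cfg.lambda_bg)))
    return treated, control


def simulate_expression(
    truth: GroundTruth, cfg: SyntheticConfig
) -> dict[str, float]:
    """Log-normal TPM-like table with a planted group effect.

    Transcripts whose 3'-UTR carries a folded planted motif are shifted
    up by ``expr_effect``; the table is renormalized to sum to 1e6.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    tids = sorted(truth.expression_group)
    values = rng.lognormal(cfg.expr_mu, cfg.expr_sigma, len(tids))
    for i, tid in enumerate(tids):
        if truth.expression_group[tid] == "og4_utr3":
            values[i] *= cfg.expr_effect
    values *= 1e6 / values.sum()
    return dict(zip(tids, values))


def simulate_anchor_sites(
    sequences: dict[str, str],
    annotations: dict[str, TranscriptAnnotation],
    truth: GroundTruth,
    cfg: SyntheticConfig,
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int]]]:
    """miRNA target intervals and poly(A) anchor positions.

    A fraction ``mirna_enrichment`` of miRNA sites is placed inside a
    ±``mirna_window`` window around planted 3'-UTR motifs; the rest are
    uniform over the 3'-UTR.  Poly(A) positions are uniform over the
    3'-UTR but kept at least ``polya_exclusion`` nt away from every
    motif (planted or chance), emulating depletion around cleavage sites.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    mirna: list[tuple[str, int, int]] = []
    polya: list[tuple[str, int]] = []
    slen = cfg.mirna_site_len

    for tid in sorted(sequences):
        ann = annotations[tid]
        a, b = ann.region_interval("UTR3")
        if b - a <= slen:
            continue
        motifs = truth.motifs_of(tid)
        utr3_motifs = [m for m in motifs if a <= m.start < b]

        for _ in range(cfg.n_mirna_per_transcript):
            if utr3_motifs and rng.random() < cfg.mirna_enrichment:
                m = utr3_motifs[rng.integers(0, len(utr3_motifs))]
                lo = max(a, m.start - cfg.mirna_window)
                hi = min(b - slen, m.end + cfg.mirna_window)
            else:
                lo, hi = a, b - slen
            if hi <= lo:
                lo, hi = a, b - slen
            s = int(rng.integers(lo, hi + 1))
            mirna.append((tid, s, s + slen))

        for _ in range(cfg.n_polya_per_transcript):
            legal = [
                p
                for p in range(a, b)
                if all(
                    p + cfg.polya_exclusion < m.start
                    or p - cfg.polya_exclusion >= m.end
                    for m in motifs
                )
            ]
            if not legal:
                raise ValueError(
                    f"{tid}: polya_exclusion={cfg.polya_exclusion} leaves "
                    f"no legal poly(A) placement in its 3'-UTR"
                )
            polya.append((tid, int(legal[rng.integers(0, len(legal))])))

    return mirna, polya
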