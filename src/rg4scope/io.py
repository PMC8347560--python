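"""Readers and writers for the pipeline's plain-text interchange formats.

All coordinates on disk are 0-based half-open (BED convention); strand is
always '+' because everything lives in transcript space.  FASTA input may
be RNA (U) or DNA (T); U is mapped to T on read with a logged note.

Formats:
  FASTA                 transcript sequences
  annotation TSV        transcript_id  utr5_end  cds_end  length
  .rtsc-style TSV       transcript_id  position  count
  .react-style TSV      transcript_id  position  theta|NA
  BED6                  transcript  start  end  name  score  +
  expression TSV        transcript_id  tpm
  truth TSV             transcript_id  start  end  region  folded  planted
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiling import TranscriptAnnotation
from .reactivity import ReactivityTrack, RTStopTrack
from .scan import G4Motif
from .synthetic import GroundTruth, PlantedMotif

log = logging.getLogger(__name__)


def _fail(path: Path | str, lineno: int, msg: str) -> None:
    raise ValueError(f"{path}:{lineno}: {msg}")


# --------------------------------------------------------------------- FASTA


def read_fasta(path: Path | str) -> dict[str, str]:
    sequences: dict[str, str] = {}
    mapped_u = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            mapped_u = True
            seq = seq.replace("U", "T")
        sequences[rec.id] = seq
    if mapped_u:
        log.info("%s: RNA alphabet detected; U mapped to T", path)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: Path | str) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- annotation


def read_annotation(path: Path | str) -> dict[str, TranscriptAnnotation]:
    out: dict[str, TranscriptAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                _fail(path, lineno, f"expected 4 columns, got {len(parts)}")
            tid, a, b, L = parts
            try:
                out[tid] = TranscriptAnnotation(tid, int(a), int(b), int(L))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return out


def write_annotation(
    annotations: Mapping[str, TranscriptAnnotation], path: Path | str
) -> None:
    with open(path, "w") as fh:
        for tid in sorted(annotations):
            ann = annotations[tid]
            fh.write(f"{tid}\t{ann.utr5_end}\t{ann.cds_end}\t{ann.length}\n")


# ----------------------------------------------------------------- rtsc/react


def read_rtsc(
    path: Path | str, lengths: Mapping[str, int] | None = None
) -> dict[str, RTStopTrack]:
    raw: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                _fail(path, lineno, f"expected 3 columns, got {len(parts)}")
            tid, pos, count = parts[0], int(parts[1]), int(parts[2])
            if pos < 0 or count < 0:
                _fail(path, lineno, "position and count must be non-negative")
            raw.setdefault(tid, {})[pos] = count
    out: dict[str, RTStopTrack] = {}
    for tid, d in raw.items():
        L = lengths[tid] if lengths else max(d) + 1
        counts = np.zeros(L, dtype=np.int64)
        for pos, c in d.items():
            if pos >= L:
                raise ValueError(
                    f"{path}: {tid} position {pos} >= declared length {L}"
                )
            counts[pos] = c
        out[tid] = RTStopTrack(tid, counts)
    return out


def write_rtsc(tracks: Mapping[str, RTStopTrack], path: Path | str) -> None:
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            for pos, c in enumerate(tracks[tid].counts):
                fh.write(f"{tid}\t{pos}\t{int(c)}\n")


def read_react(path: Path | str) -> dict[str, ReactivityTrack]:
    raw: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                _fail(path, lineno, f"expected 3 columns, got {len(parts)}")
            tid, pos = parts[0], int(parts[1])
            theta = float("nan") if parts[2] == "NA" else float(parts[2])
            raw.setdefault(tid, {})[pos] = theta
    out = {}
    for tid, d in raw.items():
        theta = np.full(max(d) + 1, np.nan)
        for pos, v in d.items():
            theta[pos] = v
        out[tid] = ReactivityTrack(tid, theta)
    return out


def write_react(tracks: Mapping[str, ReactivityTrack], path: Path | str) -> None:
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            for pos, v in enumerate(tracks[tid].theta):
                val = "NA" if np.isnan(v) else f"{v:.17g}"
                fh.write(f"{tid}\t{pos}\t{val}\n")


# ----------------------------------------------------------------------- BED


def read_bed(path: Path | str) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, "BED needs at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or start >= end:
                _fail(path, lineno, f"invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((chrom, start, end, name, score, strand))
    return out


def write_bed(
    records: Iterable[tuple[str, int, int, str, float, str]],
    path: Path | str,
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def motifs_to_bed(
    motifs: Sequence[G4Motif],
) -> list[tuple[str, int, int, str, float, str]]:
    return [
        (
            m.transcript_id,
            m.start,
            m.end,
            f"G4|q{m.quartets}|l{','.join(map(str, m.loop_lengths))}",
            float(m.quartets),
            "+",
        )
        for m in motifs
    ]


# -------------------------------------------------------------- motif tables


_MOTIF_COLS = (
    "transcript_id start end sequence tract_lengths loop_lengths "
    "region status flags"
).split()


def write_motifs(motifs: Sequence[G4Motif], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MOTIF_COLS) + "\n")
        for m in motifs:
            fh.write(
                "\t".join(
                    [
                        m.transcript_id,
                        str(m.start),
                        str(m.end),
                        m.sequence,
                        ",".join(map(str, m.tract_lengths)),
                        ",".join(map(str, m.loop_lengths)),
                        m.region,
                        m.status,
                        ";".join(m.flags) or ".",
                    ]
                )
                + "\n"
            )


def read_motifs(path: Path | str) -> list[G4Motif]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != _MOTIF_COLS:
            raise ValueError(f"{path}:1: unexpected motif table header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_MOTIF_COLS):
                _fail(path, lineno, "wrong column count")
            out.append(
                G4Motif(
                    transcript_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    sequence=parts[3],
                    tract_lengths=tuple(int(x) for x in parts[4].split(",")),
                    loop_lengths=tuple(int(x) for x in parts[5].split(",")),
                    region=parts[6],
                    status=parts[7],
                    flags=() if parts[8] == "." else tuple(parts[8].split(";")),
                )
            )
    return out


# --------------------------------------------------------- expression / truth


def read_expression(path: Path | str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                _fail(path, lineno, f"expected 2 columns, got {len(parts)}")
            out[parts[0]] = float(parts[1])
    return out


def write_expression(expression: Mapping[str, float], path: Path | str) -> None:
    with open(path, "w") as fh:
        for tid in sorted(expression):
            fh.write(f"{tid}\t{expression[tid]:.6f}\n")


def write_truth(truth: GroundTruth, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\tregion\tfolded\tplanted\n")
        for m in truth.motifs:
            fh.write(
                f"{m.transcript_id}\t{m.start}\t{m.end}\t{m.region}"
                f"\t{int(m.folded)}\t{int(m.planted)}\n"
            )


def read_truth(path: Path | str) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            tid, s, e, region, folded, planted = line.split("\t")
            truth.motifs.append(
                PlantedMotif(
                    tid, int(s), int(e), region, bool(int(folded)), bool(int(planted))
                )
            )
    return truth
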