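"""End-to-end pipeline: scan -> reactivity -> fold call -> profiling -> sampling.

``run_pipeline`` ties the stages together through the documented file
formats only, writes every declared output into an output directory, and
logs versions, seeds and parameters so a run is reproducible from its log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__, io
from .calling import FoldCallParams, call_og4
from .profiling import (
    forming_probability,
    mann_kendall,
    metagene_profile,
    region_counts_density,
    relative_density_5p,
    annotate_all,
)
from .reactivity import compute_reactivity_all
from .sampling import filter_expressed, random_sampling_test
from .scan import derive_ug4, scan_g4, summarize_motifs

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    fasta: Path
    annotation: Path
    treated_rtsc: Path
    control_rtsc: Path
    expression: Path | None = None
    mirna_bed: Path | None = None
    polya_bed: Path | None = None
    outdir: Path = Path("rg4scope_out")
    tau_fold: float = 0.5
    cap: float = 7.0
    window_5p: int = 300
    mirna_flank: int = 100
    polya_flank: int = 200
    forming_depth: int = 200
    forming_bin: int = 20
    tpm_threshold: float = 1.0
    sampling_rounds: int = 10_000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fasta", "annotation", "treated_rtsc", "control_rtsc"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
        for name in ("expression", "mirna_bed", "polya_bed"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name} input does not exist: {p}")
        self.outdir = Path(self.outdir)


def _stage(logfh, name: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    logfh.write(f"[{stamp}] === stage: {name} ===\n")
    logfh.flush()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run.log", "w") as logfh:
        logfh.write(f"rg4scope {__version__}\n")
        logfh.write(f"seed: {cfg.seed}\n")
        params = {k: str(v) for k, v in vars(cfg).items()}
        logfh.write(f"parameters: {json.dumps(params, sort_keys=True)}\n")

        _stage(logfh, "scan")
        try:
            sequences = io.read_fasta(cfg.fasta)
            annotations = io.read_annotation(cfg.annotation)
            putative = []
            for tid in sorted(sequences):
                putative.extend(scan_g4(sequences[tid], tid))
            putative = annotate_all(putative, annotations)
            io.write_motifs(putative, out / "putative_motifs.tsv")
            io.write_bed(io.motifs_to_bed(putative), out / "putative_motifs.bed")
        except Exception as exc:
            raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

        _stage(logfh, "reactivity")
        try:
            treated = io.read_rtsc(
                cfg.treated_rtsc, {t: len(s) for t, s in sequences.items()}
            )
            control = io.read_rtsc(
                cfg.control_rtsc, {t: len(s) for t, s in sequences.items()}
            )
            tracks = compute_reactivity_all(
                treated, control, sequences, cap=cfg.cap
            )
            io.write_react(tracks, out / "reactivity.react")
        except Exception as exc:
            raise RuntimeError(f"stage 'reactivity' failed: {exc}") from exc

        _stage(logfh, "call")
        try:
            og4, ug4 = call_og4(
                putative, tracks, FoldCallParams(tau_fold=cfg.tau_fold)
            )
            io.write_motifs(og4, out / "og4.tsv")
            io.write_motifs(ug4, out / "ug4.tsv")
            io.write_bed(io.motifs_to_bed(og4), out / "og4.bed")
            io.write_bed(io.motifs_to_bed(ug4), out / "ug4.bed")
        except Exception as exc:
            raise RuntimeError(f"stage 'call' failed: {exc}") from exc

        _stage(logfh, "profiling")
        try:
            stats: dict = {"motif_summary": summarize_motifs(og4)}
            stats["region"] = region_counts_density(og4, annotations)
            prof = relative_density_5p(
                [m for m in og4 if m.region == "UTR5"],
                annotations,
                window=cfg.window_5p,
            )
            with open(out / "five_prime_profile.tsv", "w") as fh:
                fh.write("position\tG\tT\tdensity\n")
                for i in range(len(prof.positions)):
                    fh.write(
                        f"{prof.positions[i]}\t{prof.G[i]}\t{prof.T[i]}"
                        f"\t{prof.d[i]:.6g}\n"
                    )
            stats["five_prime_background"] = prof.background
            lengths = {t: len(s) for t, s in sequences.items()}

            if cfg.mirna_bed is not None:
                sites = io.read_bed(cfg.mirna_bed)
                features: dict[str, list[tuple[int, int]]] = {}
                for chrom, s, e, *_ in sites:
                    features.setdefault(chrom, []).append((s, e))
                anchors = [
                    (m.transcript_id, (m.start + m.end) // 2) for m in og4
                ]
                if anchors:
                    mp = metagene_profile(
                        anchors,
                        features,
                        lengths,
                        flank=cfg.mirna_flank,
                        control_regions={
                            t: (a.cds_end, a.length)
                            for t, a in annotations.items()
                            if a.length > a.cds_end
                        },
                        seed=cfg.seed,
                    )
                    _write_profile(out / "mirna_metagene.tsv", mp)

            if cfg.polya_bed is not None:
                polya = [
                    (chrom, s) for chrom, s, e, *_ in io.read_bed(cfg.polya_bed)
                ]
                features = {}
                for m in og4:
                    features.setdefault(m.transcript_id, []).append(
                        (m.start, m.end)
                    )
                mp = metagene_profile(
                    polya,
                    features,
                    lengths,
                    flank=cfg.polya_flank,
                    control_regions={
                        t: (a.cds_end, a.length)
                        for t, a in annotations.items()
                        if a.length > a.cds_end
                    },
                    seed=cfg.seed,
                )
                _write_profile(out / "polya_metagene.tsv", mp)
                fp = forming_probability(
                    og4,
                    putative,
                    polya,
                    lengths,
                    depth=cfg.forming_depth,
                    bin_size=cfg.forming_bin,
                )
                with open(out / "forming_probability.tsv", "w") as fh:
                    fh.write("bin_start\td_obs\td_put\tp\n")
                    for i in range(len(fp.bin_starts)):
                        fh.write(
                            f"{fp.bin_starts[i]}\t{fp.d_obs[i]:.6g}"
                            f"\t{fp.d_put[i]:.6g}\t{fp.p[i]:.6g}\n"
                        )
                defined = fp.p[~np.isnan(fp.p)]
                if len(defined) >= 4:
                    mk = mann_kendall(defined)
                    stats["mann_kendall"] = {
                        "S": mk.S,
                        "varS": mk.varS,
                        "z": mk.z,
                        "p": mk.p,
                        "n": mk.n,
                    }
        except Exception as exc:
            raise RuntimeError(f"stage 'profiling' failed: {exc}") from exc

        _stage(logfh, "sampling")
        try:
            if cfg.expression is not None:
                expr = io.read_expression(cfg.expression)
                kept = filter_expressed(expr, cfg.tpm_threshold)
                og4_utr3 = {
                    m.transcript_id for m in og4 if m.region == "UTR3"
                } & kept
                others = kept - og4_utr3
                if og4_utr3 and len(others) >= 2:
                    res = random_sampling_test(
                        [expr[t] for t in sorted(og4_utr3)],
                        [expr[t] for t in sorted(others)],
                        n_rounds=cfg.sampling_rounds,
                        seed=cfg.seed,
                    )
                    np.savetxt(out / "sampling_pvalues.tsv", res.P, fmt="%.6g")
                    stats["sampling"] = {
                        "n_rounds": res.n_rounds,
                        "n_significant": res.n_significant,
                        "frac_significant": res.frac_significant,
                        "n_group": res.n_group,
                        "n_pool": res.n_pool,
                    }
        except Exception as exc:
            raise RuntimeError(f"stage 'sampling' failed: {exc}") from exc

        with open(out / "summary.json", "w") as fh:
            json.dump(stats, fh, indent=2, default=float, sort_keys=True)
        _stage(logfh, "done")
    return out


def _write_profile(path: Path, profile) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tdensity\tcontrol_density\n")
        for i, o in enumerate(profile.offsets):
            ctrl = (
                f"{profile.control_density[i]:.6g}"
                if profile.control_density is not None
                else "NA"
            )
            fh.write(f"{o}\t{profile.density[i]:.6g}\t{ctrl}\n")
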