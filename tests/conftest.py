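"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rg4scope.synthetic import (
    SyntheticConfig,
    generate_transcriptome,
    simulate_rtstops,
)


def brute_force_scan(seq: str) -> list[tuple[int, int, tuple, tuple]]:
    """Exhaustive canonical-G4 parser, independent of the scanner.

    Enumerates every (start, loop-length triple) directly on the string,
    requiring each tract to be a maximal G-run (non-G on both sides) of
    length >= 3 and each loop to be 1-7 nt.  Applies the leftmost,
    earliest-end, non-overlapping selection rule and returns
    (start, end, tract_lengths, loop_lengths) tuples.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)

    def run_len_at(pos: int) -> int:
        """Length of the maximal G-run starting exactly at pos; 0 if the
        run is extendable to the left or does not start with G."""
        if pos >= n or seq[pos] != "G":
            return 0
        if pos > 0 and seq[pos - 1] == "G":
            return 0
        j = pos
        while j < n and seq[j] == "G":
            j += 1
        return j - pos

    candidates = []
    for start in range(n):
        t1 = run_len_at(start)
        if t1 < 3:
            continue
        for l1 in range(1, 8):
            p2 = start + t1 + l1
            t2 = run_len_at(p2)
            if t2 < 3:
                continue
            for l2 in range(1, 8):
                p3 = p2 + t2 + l2
                t3 = run_len_at(p3)
                if t3 < 3:
                    continue
                for l3 in range(1, 8):
                    p4 = p3 + t3 + l3
                    t4 = run_len_at(p4)
                    if t4 < 3:
                        continue
                    end = p4 + t4
                    candidates.append(
                        (start, end, (t1, t2, t3, t4), (l1, l2, l3))
                    )

    # leftmost, then earliest end, then lexicographic parse; drop overlaps
    candidates.sort()
    chosen = []
    cursor = 0
    for cand in candidates:
        if cand[0] >= cursor:
            chosen.append(cand)
            cursor = cand[1]
    return chosen


def random_g_rich_string(rng: np.random.Generator, length: int) -> str:
    """Random string biased toward G so that motifs actually occur."""
    return "".join(
        rng.choice(np.array(list("ACGT")), size=length, p=[0.15, 0.15, 0.55, 0.15])
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared across read-only tests."""
    cfg = SyntheticConfig(n_transcripts=30, seed=11)
    sequences, annotations, truth = generate_transcriptome(cfg)
    treated, control = simulate_rtstops(sequences, truth, cfg)
    return cfg, sequences, annotations, truth, treated, control
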