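"""Shared fixtures: generated cohorts (session-scoped, so the expensive
full-scale one is built once) and independent oracle helpers."""
from __future__ import annotations

import re

import numpy as np
import pytest

from secretome_profiler import (
    CohortConfig,
    PipelineConfig,
    generate_cohort,
    run_pipeline,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """5 MAGs x 150 proteins: fast, all table kinds populated."""
    d = tmp_path_factory.mktemp("cohort_small")
    cohort = generate_cohort(CohortConfig(n_mags=5, proteins_per_mag=150, seed=11), d)
    return d, cohort


@pytest.fixture(scope="session")
def small_result(small_cohort):
    d, _ = small_cohort
    return run_pipeline(d)


@pytest.fixture(scope="session")
def full_cohort(tmp_path_factory):
    """The default noise-free benchmark cohort: 20 MAGs x 500 proteins."""
    d = tmp_path_factory.mktemp("cohort_full")
    cohort = generate_cohort(CohortConfig(seed=42), d)
    return d, cohort


# ---------------------------------------------------------------------------
# independent oracles (deliberately different code paths from the package)

_MOTIF_RE = re.compile(r"C..CH")


def sliding_window_motifs(seq: str) -> list[int]:
    """5-residue sliding-window CxxCH oracle (1-based starts, overlaps kept)."""
    return [i + 1 for i in range(len(seq)) if _MOTIF_RE.fullmatch(seq[i : i + 5])]


def dp_local_score(a: str, b: str, score, gap_open=-11.0, gap_extend=-1.0) -> float:
    """Exhaustive affine-gap local-alignment score oracle (three-state Gotoh,
    no traceback, written independently of the engine)."""
    neg = float("-inf")
    la, lb = len(a), len(b)
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend)
            M[i][j] = max(0.0, M[i - 1][j - 1] + score(a[i - 1], b[j - 1]), X[i][j], Y[i][j])
            best = max(best, M[i][j])
    return best


def bfs_closure(seed_ids, edges, accept_ids, candidate_ids):
    """Domain-filtered BFS closure oracle for the iterative expansion.

    edges: (query, subject) pairs at or below the cutoff. A candidate is
    accepted (with its BFS round) if it reaches the current database and has
    an accept domain; domain-negative candidates never join the database, so
    nothing can propagate through them.
    """
    db = set(seed_ids)
    accepted = {}
    discarded = set()
    rnd = 0
    while True:
        rnd += 1
        frontier = {
            q for q, s in edges
            if s in db and q in candidate_ids
            and q not in db and q not in accepted and q not in discarded
        }
        if not frontier:
            return accepted
        for q in sorted(frontier):
            if q in accept_ids:
                accepted[q] = rnd
                db.add(q)
            else:
                discarded.add(q)


def upgma_heights(dist: np.ndarray) -> list[float]:
    """Brute-force average-linkage merge heights from a square distance
    matrix, recomputing inter-cluster means at every step."""
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(np.mean([[dist[a, b] for b in clusters[j]] for a in clusters[i]]))
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights
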