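"""Shared fixtures and independent reference implementations used as oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pelitox.library_io import (
    BiomarkerEntry,
    BiomarkerLibrary,
    PlateLayout,
    PlateTimeSeries,
    load_default_library,
)


@pytest.fixture(scope="session")
def library74() -> BiomarkerLibrary:
    return load_default_library()


@pytest.fixture(scope="session")
def small_library() -> BiomarkerLibrary:
    """Ten reporters, two per stress category."""
    cats = ["general", "chemical", "DNA", "oxidative", "protein"]
    entries = []
    for i in range(10):
        cat = cats[i // 2]
        entries.append(
            BiomarkerEntry(
                orf_id=f"YTEST{i:03d}W",
                gene_name=f"GEN{i}",
                category=cat,
                ontology_terms=frozenset({f"term_{cat}", "cellular response to stress"}),
            )
        )
    return BiomarkerLibrary(entries)


def make_plate(
    well_specs: list[tuple],
    time_min=(0.0, 60.0, 120.0),
) -> PlateTimeSeries:
    """Build a tiny plate from (well, role, orf, compound, conc, rep, od_fn, gfp_fn).

    ``od_fn``/``gfp_fn`` are either scalars (constant traces) or callables of
    the time vector.
    """
    t = np.asarray(time_min, dtype=float)
    rows, od_rows, gfp_rows = [], [], []
    for well, role, orf, compound, conc, rep, od_fn, gfp_fn in well_specs:
        rows.append((well, role, orf, compound, conc, rep))
        od_rows.append(od_fn(t) if callable(od_fn) else np.full_like(t, od_fn))
        gfp_rows.append(gfp_fn(t) if callable(gfp_fn) else np.full_like(t, gfp_fn))
    layout = PlateLayout(
        pd.DataFrame(
            rows,
            columns=["well", "role", "orf", "compound", "concentration_mg_L", "replicate"],
        )
    )
    wells = [r[0] for r in rows]
    return PlateTimeSeries(
        time_min=t,
        od=pd.DataFrame(od_rows, index=wells, columns=t),
        gfp=pd.DataFrame(gfp_rows, index=wells, columns=t),
        layout=layout,
    )


def naive_average_linkage(X: np.ndarray) -> list[tuple[frozenset, float]]:
    """O(n^3) agglomerative average linkage on correlation distance.

    Returns merges as (leaf-member set, height), the representation compared
    against the production dendrogram. Deliberately independent of scipy's
    clustering: distances are recomputed from scratch at every step as the
    mean pairwise original distance between cluster members.
    """
    n = X.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                dist[i, j] = 1.0 - r
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for a_pos, a in enumerate(ids):
            for b in ids[a_pos + 1:]:
                d = float(
                    np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[next_id] = merged
        merges.append((merged, d))
        next_id += 1
    return merges
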