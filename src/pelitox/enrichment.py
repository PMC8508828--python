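"""Stress-category GSEA with empirical nulls, and library-referenced ontology
enrichment.

GSEA ranks all library ORFs by PELI (descending; ties broken by a seeded
shuffle) and scores a category's member set with the weighted
Kolmogorov-Smirnov running-sum enrichment score, weight |PELI - 1|^p with
exponent p = 1 by default (an unweighted variant is selectable; it is the
one whose p-values are exactly rank-invariant). The null is empirical:
random member sets of equal size drawn from the library, and
p = (1 + #{null >= observed}) / (1 + n_perm). An exhaustive mode enumerates
every subset when that is feasible.

Ontology enrichment follows the network-ontology-analysis convention: the
reporter library itself is the reference universe, the activated ORFs
(PELI_ORF > 1.5) the test set, and each term gets an upper-tail
hypergeometric p-value. Terms are flat sets (no ancestor propagation);
significance defaults to p < 0.05 uncorrected, with Benjamini-Hochberg
selectable.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from pelitox.library_io import BiomarkerLibrary, ValidationError

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 200_000  # max subsets enumerated in exhaustive mode


@dataclasses.dataclass
class EnrichmentResult:
    set_id: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    test_set_size: int = 0
    reference_size: int = 0
    overlap: int = 0
    significant: bool = False


def _enrichment_scores(masks: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted-KS enrichment scores for member masks in ranked order.

    ``masks``: (k, N) boolean, True at member positions of the ranked list.
    Returns the signed running-sum deviation of maximal magnitude per row.
    """
    k, n = masks.shape
    m = int(masks[0].sum())
    w = np.broadcast_to(weights, (k, n)).copy()
    wm = np.where(masks, w, 0.0)
    totals = wm.sum(axis=1)
    flat = totals <= 0  # all-tied input: fall back to unweighted steps
    if flat.any():
        wm[flat] = masks[flat].astype(float)
        totals[flat] = m
    hit = wm / totals[:, None]
    miss = (~masks) / float(n - m)
    run = np.cumsum(hit - miss, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(k), idx]


def _ranked_mask(
    orf_pelis: Mapping[str, float],
    members: set[str],
    rng: np.random.Generator,
    weight_exponent: float,
    weighting: str,
) -> tuple[np.ndarray, np.ndarray]:
    orfs = sorted(orf_pelis)
    values = np.array([orf_pelis[o] for o in orfs], dtype=float)
    shuffle = rng.permutation(len(orfs))  # seeded tie-break
    order = shuffle[np.argsort(-values[shuffle], kind="stable")]
    ranked_orfs = [orfs[i] for i in order]
    if weighting == "abs_dev":
        weights = np.abs(values[order] - 1.0) ** weight_exponent
    elif weighting == "unweighted":
        weights = np.ones(len(orfs))
    else:
        raise ValidationError(f"unknown GSEA weighting {weighting!r}")
    mask = np.array([o in members for o in ranked_orfs])
    return mask, weights


def gsea_category(
    orf_pelis: Mapping[str, float],
    members: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    weighting: str = "abs_dev",
    method: str = "permutation",
    set_id: str = "",
) -> EnrichmentResult:
    """Enrichment of one stress category's member set in the PELI ranking.

    ``method="permutation"`` draws ``n_perm`` seeded random member sets of
    equal size; ``method="exhaustive"`` enumerates every subset (small
    libraries only) and returns the exact enumeration tail fraction.
    """
    members = set(members)
    universe = set(orf_pelis)
    if not members <= universe:
        raise ValidationError(
            f"members not in the ranked library: {sorted(members - universe)[:10]}"
        )
    if len(members) < 2:
        raise ValidationError("GSEA member set needs >= 2 ORFs")
    if method == "permutation" and n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if seed is None:
        raise ValidationError("GSEA requires a seed")

    rng = np.random.default_rng(seed)
    mask, weights = _ranked_mask(orf_pelis, members, rng, weight_exponent, weighting)
    n, m = len(mask), int(mask.sum())
    observed = float(_enrichment_scores(mask[None, :], weights)[0])

    if method == "exhaustive":
        n_subsets = math.comb(n, m)
        if n_subsets > EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"{n_subsets} subsets exceed the exhaustive enumeration limit"
            )
        masks = np.zeros((n_subsets, n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), m)):
            masks[i, list(combo)] = True
        null = _enrichment_scores(masks, weights)
        p = float(np.mean(null >= observed - 1e-12))
        n_used = n_subsets
    elif method == "permutation":
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.choice(n, size=m, replace=False)] = True
        null = _enrichment_scores(masks, weights)
        p = float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_perm))
        n_used = n_perm
    else:
        raise ValidationError(f"unknown GSEA method {method!r}")

    return EnrichmentResult(
        set_id=set_id,
        statistic=observed,
        p_value=p,
        n_permutations=n_used,
        test_set_size=m,
        reference_size=n,
        significant=p < 0.05,
    )


def ontology_enrichment(
    test_set: Iterable[str],
    library: BiomarkerLibrary,
    term_map: Mapping[str, set[str]] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the test set.

    The reference universe is the whole library; ``term_map`` defaults to
    the library's own ontology annotations. ``correction="bh"`` applies
    Benjamini-Hochberg to the significance flags (p-values stay raw).
    """
    test_set = set(test_set)
    universe = set(library.orfs)
    if not test_set <= universe:
        raise ValidationError(
            f"test set not a subset of the library: {sorted(test_set - universe)[:10]}"
        )
    if term_map is None:
        term_map = library.term_map()
    if not test_set:
        logger.info("empty test set: no activated ORFs, returning no enrichments")
        return []
    n_universe = len(universe)
    n_test = len(test_set)
    results = []
    for term in sorted(term_map):
        annotated = set(term_map[term]) & universe
        k_term = len(annotated)
        if k_term == 0:
            continue
        overlap = len(annotated & test_set)
        p = float(hypergeom.sf(overlap - 1, n_universe, k_term, n_test))
        results.append(
            EnrichmentResult(
                set_id=term,
                statistic=float(overlap),
                p_value=p,
                test_set_size=n_test,
                reference_size=n_universe,
                overlap=overlap,
                significant=p < alpha,
            )
        )
    if correction == "bh":
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        n = len(ps)
        passed = np.zeros(n, dtype=bool)
        thresh = alpha * (np.arange(1, n + 1)) / n
        below = ps[order] <= thresh
        if below.any():
            cutoff = np.max(np.nonzero(below)[0])
            passed[order[: cutoff + 1]] = True
        for r, ok in zip(results, passed):
            r.significant = bool(ok)
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    return results


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV of ``term<TAB>orf`` association pairs."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"term", "orf"} - set(df.columns)
    if missing:
        raise ValidationError(f"term map missing columns: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.term, set()).add(row.orf)
    return out


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tidy table of enrichment results with the '*' significance convention."""
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(
        rows,
        columns=[f.name for f in dataclasses.fields(EnrichmentResult)],
    )
    df["flag"] = np.where(df["significant"], "*", "") if len(df) else []
    return df
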