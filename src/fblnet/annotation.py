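"""Statistical comparisons of annotated gene classes against network structure.

Workflows mirroring the downstream analyses run on human signaling
networks: compare the proportion of functionally important genes
(essential / disease / drug-target) between the NFD and non-NFD groups,
sweep a threshold β over the perturbation-sustainable probability γ and
track the annotated proportion among candidates {v : γ(v) ≥ β}, and
contrast the observed group difference with a degree-preserving rewiring
null model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportions_ztest

from .network import DirectedNetwork, NodeClassification, classify_nodes
from .synthetic import rewire_preserving_degrees

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """Named gene sets (categories may overlap)."""

    categories: Mapping[str, frozenset[str]]

    def restrict_to(self, nodes: frozenset[str]) -> "GeneAnnotation":
        """Drop genes absent from the network (count logged per category)."""
        out = {}
        for cat, genes in self.categories.items():
            kept = genes & nodes
            dropped = len(genes) - len(kept)
            if dropped:
                logger.info("%s: %d annotated gene(s) not in network, dropped", cat, dropped)
            out[cat] = kept
        return GeneAnnotation(categories=out)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group annotated-proportion comparison (NFD vs non-NFD)."""

    category: str
    n_nfd: int
    n_non_nfd: int
    k_nfd: int
    k_non_nfd: int
    p_value: float

    @property
    def prop_nfd(self) -> float:
        return self.k_nfd / self.n_nfd

    @property
    def prop_non_nfd(self) -> float:
        return self.k_non_nfd / self.n_non_nfd


def load_annotations(paths: Mapping[str, str | Path]) -> GeneAnnotation:
    """Read one plain-text gene list per category (one identifier per line).

    Blank lines and ``#`` comments are skipped; duplicates deduplicate.
    """
    cats = {}
    for cat, p in paths.items():
        p = Path(p)
        genes = {
            line.strip()
            for line in p.read_text().splitlines()
            if line.strip() and not line.strip().startswith("#")
        }
        cats[cat] = frozenset(genes)
    return GeneAnnotation(categories=cats)


def compare_groups(
    cls: NodeClassification,
    all_nodes: frozenset[str],
    ann: GeneAnnotation,
    category: str,
    test: str = "ztest",
) -> GroupComparison:
    """Compare annotated proportions between the NFD and non-NFD node groups.

    ``test`` selects a two-sided two-proportion z-test (default) or
    Fisher's exact test.
    """
    genes = ann.categories[category] & all_nodes
    nfd = cls.is_nfd
    non_nfd = all_nodes - nfd
    if not nfd or not non_nfd:
        raise ValueError("both the NFD and non-NFD groups must be non-empty")
    k_nfd = len(genes & nfd)
    k_non = len(genes & non_nfd)
    if test == "ztest":
        if k_nfd + k_non in (0, len(nfd) + len(non_nfd)):
            p = 1.0  # identical degenerate proportions; the z-statistic is undefined
        else:
            _, p = proportions_ztest(
                count=np.array([k_nfd, k_non]),
                nobs=np.array([len(nfd), len(non_nfd)]),
                alternative="two-sided",
            )
    elif test == "fisher":
        _, p = fisher_exact(
            [[k_nfd, len(nfd) - k_nfd], [k_non, len(non_nfd) - k_non]],
            alternative="two-sided",
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        category=category,
        n_nfd=len(nfd),
        n_non_nfd=len(non_nfd),
        k_nfd=k_nfd,
        k_non_nfd=k_non,
        p_value=float(p),
    )


def threshold_sweep(
    scores: Mapping[str, float],
    ann: GeneAnnotation,
    betas: Sequence[float] | None = None,
    max_beta: float | None = None,
) -> pd.DataFrame:
    """Candidate-set size and annotated proportions over a γ-threshold grid.

    For each threshold β the candidate set is {v : γ(v) ≥ β}.  With
    ``betas=None`` the grid is the sorted distinct observed γ values
    (optionally truncated at ``max_beta``).  Returns a DataFrame with
    columns ``beta``, ``n_candidates`` and one proportion column per
    category (NaN when the candidate set is empty).
    """
    if betas is None:
        grid = sorted(set(scores.values()))
        if max_beta is not None:
            grid = [b for b in grid if b <= max_beta]
    else:
        grid = list(betas)
        if any(b < 0 or b > 1 for b in grid):
            raise ValueError("thresholds must lie in [0, 1]")
        if grid != sorted(grid):
            raise ValueError("thresholds must be sorted ascending")
    nodes = list(scores)
    rows = []
    for beta in grid:
        cand = {v for v in nodes if scores[v] >= beta}
        row: dict[str, float] = {"beta": beta, "n_candidates": len(cand)}
        for cat, genes in ann.categories.items():
            row[f"prop_{cat}"] = len(cand & genes) / len(cand) if cand else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def rewired_control(
    net: DirectedNetwork,
    ann: GeneAnnotation,
    n_random: int = 100,
    seed: int = 0,
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """Group-difference distribution over degree-preserving rewired replicas.

    Each replicate rewires the network (annotations stay attached to the
    nodes), reclassifies, and records the non-NFD minus NFD annotated-
    proportion difference per category.  Comparing the observed difference
    to this distribution shows whether annotated genes are placed
    non-randomly with respect to feedback-loop structure.
    """
    if n_swaps is None:
        n_swaps = 10 * net.n_edges
    rows = []
    for r in range(n_random):
        rep = rewire_preserving_degrees(net, n_swaps=n_swaps, seed=(seed * 9973 + r) % (2**31))
        cls = classify_nodes(rep)
        row: dict[str, float] = {"replicate": r}
        for cat in ann.categories:
            try:
                cmpres = compare_groups(cls, rep.nodes, ann, cat)
                row[f"diff_{cat}"] = cmpres.prop_non_nfd - cmpres.prop_nfd
            except ValueError:
                row[f"diff_{cat}"] = math.nan
        rows.append(row)
    columns = ["replicate"] + [f"diff_{c}" for c in ann.categories]
    return pd.DataFrame(rows, columns=columns)


def empirical_percentile(observed: float, null_values: Sequence[float]) -> float:
    """Fraction of null replicates at or below the observed value."""
    vals = [v for v in null_values if not math.isnan(v)]
    if not vals:
        raise ValueError("no finite null values")
    return sum(v <= observed for v in vals) / len(vals)
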