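"""Functional-term scoring from interaction-level annotations.

A term annotates an *interaction* when both endpoint genes carry it
(F_ij = F_i ∩ F_j).  A term's probability under a walk is the cumulative
visitation probability of the interactions carrying it, and its score is
the log-ratio between the data-biased and the uniform-baseline walk:

    p(f) = sum_{ij in f} e_ij,      s(f) = log( p_w(f) / p_r(f) )

The baseline denominator absorbs the bias from network topology (heavily
studied hub genes) and from annotation set size, so s(f) reads as a
relative visitation probability of the term's subnetwork.  Terms the
baseline walk never visits (no annotated connected gene pair) have an
undefined score, reported as NaN rather than zero.

Also here: the interaction-count / ontology-level term filter and an exact
hypergeometric enrichment utility with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

from .network import AnnotationMap, InteractionNetwork
from .walk import (DEFAULT_MAX_ITER, DEFAULT_Q, DEFAULT_TOL, EdgeFluxResult,
                   baseline_walk, edge_flux)

logger = logging.getLogger("edgeflux")

__all__ = [
    "InteractionAnnotation",
    "TermScores",
    "annotate_interactions",
    "term_walk_scores",
    "filter_terms",
    "hypergeometric_tail",
    "hypergeometric_enrichment",
    "benjamini_hochberg",
]


@dataclass
class InteractionAnnotation:
    """Term sets at the interaction level.

    ``edge_terms`` maps a canonical edge key (a, b, directed) to the terms
    shared by both endpoints; ``term_edge_counts`` counts, per term, the
    network edges carrying it.
    """

    edge_terms: dict[tuple, frozenset[str]]
    term_edge_counts: dict[str, int]
    levels: dict[str, float] | None = None
    term_names: dict[str, str] = field(default_factory=dict)

    def edges_for_term(self, term: str) -> list[tuple]:
        return sorted(k for k, terms in self.edge_terms.items() if term in terms)

    def edges_for_terms(self, terms: Iterable[str]) -> list[tuple]:
        wanted = set(terms)
        return sorted(k for k, ts in self.edge_terms.items() if ts & wanted)


def annotate_interactions(network: InteractionNetwork,
                          annotation: AnnotationMap,
                          propagate_ancestors: bool = True
                          ) -> InteractionAnnotation:
    """Intersect endpoint term sets for every edge (F_ij = F_i ∩ F_j).

    With ``propagate_ancestors`` (and an ontology present) each gene is
    first annotated to all ancestors of its terms, the standard true-path
    reading of ontology annotations.  Unannotated genes yield empty
    intersections on all their edges.
    """
    if propagate_ancestors and annotation.ontology_parents:
        annotation = annotation.propagate_to_ancestors()
    gene_terms = annotation.gene_to_terms()
    empty: frozenset[str] = frozenset()
    edge_terms: dict[tuple, frozenset[str]] = {}
    counts: dict[str, int] = {}
    for key in network.canonical_edge_keys():
        a, b, _ = key
        shared = gene_terms.get(a, empty) & gene_terms.get(b, empty)
        edge_terms[key] = shared
        for t in shared:
            counts[t] = counts.get(t, 0) + 1
    return InteractionAnnotation(edge_terms=edge_terms,
                                 term_edge_counts=counts,
                                 levels=annotation.levels,
                                 term_names=dict(annotation.term_names))


@dataclass
class TermScores:
    """Per-term walk scores for one condition."""

    score: dict[str, float]      # s(f), NaN when baseline never visits f
    p_weighted: dict[str, float]
    p_baseline: dict[str, float]
    edge_count: dict[str, int]
    levels: dict[str, float] | None = None
    term_names: dict[str, str] = field(default_factory=dict)

    def top_terms(self, k: int = 10) -> list[tuple[str, float]]:
        defined = [(t, s) for t, s in self.score.items() if not math.isnan(s)]
        return sorted(defined, key=lambda ts: (-ts[1], ts[0]))[:k]


def _edge_prob_symmetrized(flux: EdgeFluxResult, keys: Iterable[tuple],
                           which: str) -> dict[tuple, float]:
    probs = (flux.edge_prob_weighted if which == "w"
             else flux.edge_prob_baseline)
    out = {}
    for key in keys:
        a, b, directed = key
        if directed:
            out[key] = probs.get((a, b), 0.0)
        else:
            out[key] = probs.get((a, b), 0.0) + probs.get((b, a), 0.0)
    return out


def term_walk_scores(network: InteractionNetwork,
                     weights: Mapping[str, float],
                     interaction_annotation: InteractionAnnotation,
                     q: float = DEFAULT_Q,
                     tol: float = DEFAULT_TOL,
                     max_iter: int = DEFAULT_MAX_ITER,
                     log_base: float = math.e,
                     flux: EdgeFluxResult | None = None,
                     baseline=None) -> TermScores:
    """Score every term: s(f) = log of weighted vs baseline cumulative
    interaction probability.

    Reuses an :class:`EdgeFluxResult` when given (the walks are shared
    between edge and term scoring); otherwise runs them.  Edge counts are
    counted within the loaded network.
    """
    if flux is None:
        flux = edge_flux(network, weights, q=q, tol=tol, max_iter=max_iter,
                         log_base=log_base, baseline=baseline)
    keys = list(interaction_annotation.edge_terms)
    ew = _edge_prob_symmetrized(flux, keys, "w")
    er = _edge_prob_symmetrized(flux, keys, "r")
    p_w: dict[str, float] = {}
    p_r: dict[str, float] = {}
    for key, terms in interaction_annotation.edge_terms.items():
        if not terms:
            continue
        pw, pr = ew[key], er[key]
        for t in terms:
            p_w[t] = p_w.get(t, 0.0) + pw
            p_r[t] = p_r.get(t, 0.0) + pr
    scale = math.log(flux.log_base)
    # every annotation term is reported; no carrying edge (p_r = 0) -> NaN
    all_terms = (set(interaction_annotation.term_names)
                 | set(interaction_annotation.term_edge_counts))
    score: dict[str, float] = {}
    for t in all_terms:
        num, den = p_w.get(t, 0.0), p_r.get(t, 0.0)
        score[t] = math.log(num / den) / scale if (den > 0 and num > 0) else math.nan
    return TermScores(score=score, p_weighted=p_w, p_baseline=p_r,
                      edge_count={t: interaction_annotation.term_edge_counts.get(t, 0)
                                  for t in all_terms},
                      levels=interaction_annotation.levels,
                      term_names=dict(interaction_annotation.term_names))


def filter_terms(scores: TermScores, min_edges: int = 6,
                 min_level: int = 6) -> TermScores:
    """Drop generic / weakly supported terms.

    Retains terms with at least ``min_edges`` carrying interactions AND
    ontology level at least ``min_level`` (shallow terms like "nucleus" are
    too generic).  Either threshold is disabled by 0; boundary values are
    retained.
    """
    if min_level > 0 and scores.levels is None:
        raise ValueError("min_level > 0 requires ontology levels; load an "
                         "ontology or pass min_level=0")
    keep = set()
    for t in scores.score:
        if min_edges > 0 and scores.edge_count.get(t, 0) < min_edges:
            continue
        if min_level > 0:
            lvl = scores.levels.get(t, math.inf)
            if not (lvl >= min_level):
                continue
        keep.add(t)
    sub = lambda d: {t: v for t, v in d.items() if t in keep}
    return TermScores(score=sub(scores.score),
                      p_weighted=sub(scores.p_weighted),
                      p_baseline=sub(scores.p_baseline),
                      edge_count=sub(scores.edge_count),
                      levels=sub(scores.levels) if scores.levels else scores.levels,
                      term_names=sub(scores.term_names))


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    Integer combinatorics (no floating summation): the result is the float
    nearest the exact rational probability.
    """
    if k <= 0:
        return 1.0
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return float(Fraction(acc, total))


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Step-up FDR adjustment; monotone, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def hypergeometric_enrichment(selected_genes: Iterable[str],
                              annotation: AnnotationMap,
                              universe: Iterable[str]
                              ) -> dict[str, dict[str, float]]:
    """Per-term over-representation of a gene selection.

    For each term with any gene in the universe: upper-tail hypergeometric
    probability of seeing at least the observed overlap, plus BH-adjusted
    q-values across the tested terms.  Returns
    term -> {p, q, k, K, n, N}.
    """
    universe = set(universe)
    selected = set(selected_genes)
    if not selected:
        raise ValueError("empty gene selection")
    stray = selected - universe
    if stray:
        raise ValueError(
            f"selected genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selected)
    terms, pvals, rows = [], [], {}
    for term in sorted(annotation.term_to_genes):
        members = annotation.term_to_genes[term] & universe
        if not members:
            continue
        K = len(members)
        k = len(members & selected)
        p = hypergeometric_tail(k, N, K, n)
        terms.append(term)
        pvals.append(p)
        rows[term] = {"p": p, "k": float(k), "K": float(K),
                      "n": float(n), "N": float(N)}
    for term, qv in zip(terms, benjamini_hochberg(pvals)):
        rows[term]["q"] = qv
    return rows
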