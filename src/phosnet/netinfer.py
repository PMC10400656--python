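"""Dynamic-Bayesian-network inference of signed regulator-target edges.

Inference runs per condition in three steps:

1. **Candidate discovery.**  Only phosphosites on proteins annotated as
   kinase or phosphatase may regulate.  A regulator site r is a candidate
   parent of target p when their ternary delta-event series agree —
   r_delta(t) = p_delta(t) (time-lapse 0) or r_delta(t-1) = p_delta(t)
   (time-lapse 1) — for strictly more than half of the comparable
   transitions.  Agreement includes 0 = 0: co-stability counts.
2. **Scoring.**  Every single candidate and every unordered candidate
   pair (each parent keeping its own lapse) is scored with the Bayesian
   Dirichlet equivalent uniform (BDeu) marginal likelihood over the
   replicate-level 3-state series; the best-scoring parent set wins.
   The Dirichlet hyperparameter is tiny (alpha = 1e-15) so the score
   strongly rewards near-deterministic parent-child level mappings.
3. **Sign assignment.**  Over transitions where both regulator and
   target events are nonzero, a majority of co-directional changes means
   phosphorylation, a majority of anti-directional changes means
   dephosphorylation, and a tie is undetermined.

Self-edges and edges between two sites of the same protein are excluded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .discretize import N_LEVELS

logger = logging.getLogger(__name__)

PHOS = "phos"
DEPHOS = "dephos"
UNDETERMINED = "undetermined"

AS_PRINTED = "as_printed"
STANDARD = "standard"


@dataclass(frozen=True)
class BDeuParams:
    """BDeu hyperparameters.

    ``alpha`` is the total Dirichlet prior mass; ``formula_variant``
    selects between the published scoring formula (``"as_printed"``,
    which uses alpha/q_i inside the per-level gamma terms) and canonical
    BDeu (``"standard"``, alpha/(r_i q_i)).  At alpha = 1e-15 the two
    differ only through zero-count terms.
    """

    alpha: float = 1e-15
    formula_variant: str = AS_PRINTED

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.formula_variant not in (AS_PRINTED, STANDARD):
            raise ValueError(f"unknown formula_variant {self.formula_variant!r}")


@dataclass(frozen=True)
class CandidatePair:
    regulator: tuple
    target: tuple
    lapse: int
    concordance: float


@dataclass(frozen=True)
class SignedEdge:
    regulator: tuple
    target: tuple
    sign: str
    lapse: int
    score: float
    condition: object


# ---------------------------------------------------------------------------
# Concordance (candidate discovery)


def concordance(r_delta: np.ndarray, p_delta: np.ndarray, lapse: int) -> float:
    """Fraction of comparable transitions where the event series agree.

    Lapse 0 compares r(t) with p(t) over all transitions; lapse 1
    compares r(t-1) with p(t), losing the first transition.  Values of 0
    on both sides count as agreement.
    """
    r = np.asarray(r_delta)
    p = np.asarray(p_delta)
    if r.shape != p.shape:
        raise ValueError("delta series must share length")
    if lapse == 0:
        pairs = r == p
    elif lapse == 1:
        if r.size < 2:
            return 0.0
        pairs = r[:-1] == p[1:]
    else:
        raise ValueError("lapse must be 0 or 1")
    return float(pairs.mean()) if pairs.size else 0.0


def find_candidates(
    deltas: pd.DataFrame,
    regulator_sites,
    site_protein: dict | None = None,
    threshold: float = 0.5,
    lapses=(0, 1),
) -> list[CandidatePair]:
    """All regulator-target pairs whose concordance strictly exceeds
    ``threshold`` at some lapse (each qualifying lapse kept separately).

    ``deltas`` is a site x transition frame of ternary events for one
    condition; ``regulator_sites`` lists the site keys allowed to have
    out-edges; ``site_protein`` maps site key -> protein id (defaults to
    the first element of the site-key tuple) for the same-protein
    exclusion.
    """
    regulator_sites = [s for s in regulator_sites if s in deltas.index]
    if not regulator_sites:
        logger.warning("no regulator sites among the network sites; no candidates")
        return []
    if site_protein is None:
        site_protein = {s: s[0] if isinstance(s, tuple) else s for s in deltas.index}
    arr = {s: deltas.loc[s].to_numpy() for s in deltas.index}
    out = []
    for target in deltas.index:
        for reg in regulator_sites:
            if reg == target or site_protein[reg] == site_protein[target]:
                continue
            for lapse in lapses:
                c = concordance(arr[reg], arr[target], lapse)
                if c > threshold:
                    out.append(CandidatePair(reg, target, lapse, c))
    return out


# ---------------------------------------------------------------------------
# BDeu scoring


def _data_vectors(
    target_levels: np.ndarray, parents: list[tuple[np.ndarray, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Pair target states at t with parent states at t - lapse.

    Arrays are (replicate, time); time indices whose lagged parent state
    falls outside the grid are dropped.  Returns (child values, parent
    configuration codes) flattened over (replicate, time).
    """
    if target_levels.ndim != 2:
        raise ValueError("level arrays must be (replicate, time)")
    T = target_levels.shape[1]
    max_lapse = max((lp for _, lp in parents), default=0)
    ts = np.arange(max_lapse, T)
    if ts.size == 0:
        raise ValueError("no comparable time points for this lapse structure")
    child = target_levels[:, ts].ravel()
    config = np.zeros_like(child, dtype=np.int64)
    for levels, lapse in parents:
        if levels.shape != target_levels.shape:
            raise ValueError("parent and target level series must share shape")
        config = config * N_LEVELS + levels[:, ts - lapse].ravel()
    return child, config


def bdeu_score(
    target_levels: np.ndarray,
    parents: list[tuple[np.ndarray, int]],
    params: BDeuParams = BDeuParams(),
) -> float:
    """BDeu marginal-likelihood score of ``parents -> target``.

    ``target_levels`` and each parent's levels are (replicate, time)
    int arrays over the 3 states; each parent carries its own time
    lapse.  The j-sum runs over all q_i = 3^|parents| parent
    configurations, observed or not.
    """
    if not 1 <= len(parents) <= 2:
        raise ValueError("parent sets of size 1 or 2 only")
    child, config = _data_vectors(target_levels, parents)
    if child.size == 0:
        raise ValueError("empty data-vector set")
    q_i = N_LEVELS ** len(parents)
    r_i = N_LEVELS
    counts = np.zeros((q_i, r_i))
    np.add.at(counts, (config, child), 1.0)
    a_j = params.alpha / q_i
    a_jk = params.alpha / (r_i * q_i)
    inner = a_j if params.formula_variant == AS_PRINTED else a_jk
    n_j = counts.sum(axis=1)
    score = (
        gammaln(a_j) * q_i
        - gammaln(n_j + a_j).sum()
        + gammaln(counts + inner).sum()
        - gammaln(a_jk) * (q_i * r_i)
    )
    return float(score)


def select_parent_set(
    target: tuple,
    candidates: list[CandidatePair],
    levels_of,
    params: BDeuParams = BDeuParams(),
    max_parents: int = 2,
) -> tuple[tuple[CandidatePair, ...], float] | None:
    """Best-scoring parent set for one target, or None without candidates.

    ``levels_of`` maps a site key to its (replicate, time) level array.
    All single candidates and all unordered pairs of candidates on
    distinct regulators are scored; ties break toward higher score, then
    fewer parents, then lexicographically smaller regulator keys.
    """
    cands = [c for c in candidates if c.target == target]
    if not cands:
        return None
    tgt_levels = levels_of(target)
    scored = []
    sets: list[tuple[CandidatePair, ...]] = [(c,) for c in cands]
    if max_parents >= 2:
        sets += [
            pair
            for pair in itertools.combinations(cands, 2)
            if pair[0].regulator != pair[1].regulator
        ]
    for parent_set in sets:
        parents = [(levels_of(c.regulator), c.lapse) for c in parent_set]
        score = bdeu_score(tgt_levels, parents, params)
        # scores equal up to floating-point noise count as tied; ties
        # prefer fewer parents, then stronger temporal concordance, then
        # a deterministic lexicographic order
        key = (
            -round(score, 6),
            len(parent_set),
            -sum(c.concordance for c in parent_set) / len(parent_set),
            tuple(sorted((c.regulator, c.lapse) for c in parent_set)),
        )
        scored.append((key, parent_set, score))
    key, best, score = min(scored, key=lambda x: x[0])
    return best, score


# ---------------------------------------------------------------------------
# Sign rule


def assign_sign(
    regulator_deltas: np.ndarray, target_deltas: np.ndarray, lapse: int
) -> str:
    """Majority direction over transitions where both events are nonzero."""
    r = np.asarray(regulator_deltas)
    p = np.asarray(target_deltas)
    if lapse == 1:
        r, p = r[:-1], p[1:]
    elif lapse != 0:
        raise ValueError("lapse must be 0 or 1")
    both = (r != 0) & (p != 0)
    same = int(((r == p) & both).sum())
    opposite = int(((r == -p) & both).sum())
    if same > opposite:
        return PHOS
    if opposite > same:
        return DEPHOS
    return UNDETERMINED


# ---------------------------------------------------------------------------
# Per-condition networks


def infer_condition_network(
    deltas: pd.DataFrame,
    level_arrays: dict,
    regulator_sites,
    condition,
    site_protein: dict | None = None,
    params: BDeuParams = BDeuParams(),
    threshold: float = 0.5,
    lapses=(0, 1),
    max_parents: int = 2,
) -> nx.DiGraph:
    """Infer one condition's signed network.

    ``deltas`` holds each selected site's ternary events, ``level_arrays``
    maps site key -> (replicate, time) 3-state array.  Every selected
    site is tried as a target; its best BDeu parent set contributes one
    signed edge per parent.
    """
    candidates = find_candidates(
        deltas, regulator_sites, site_protein=site_protein,
        threshold=threshold, lapses=lapses,
    )
    by_target: dict = {}
    for c in candidates:
        by_target.setdefault(c.target, []).append(c)
    reg_set = set(regulator_sites)
    g = nx.DiGraph(condition=condition)
    for site in deltas.index:
        g.add_node(site, is_regulator=site in reg_set)
    darr = {s: deltas.loc[s].to_numpy() for s in deltas.index}
    for target, cands in sorted(by_target.items()):
        best = select_parent_set(
            target, cands, level_arrays.__getitem__, params, max_parents
        )
        if best is None:
            continue
        parent_set, score = best
        for c in parent_set:
            sign = assign_sign(darr[c.regulator], darr[target], c.lapse)
            g.add_edge(
                c.regulator,
                target,
                sign=sign,
                lapse=c.lapse,
                score=score,
                concordance=c.concordance,
                condition=condition,
            )
    return g


def combine_networks(net_a: nx.DiGraph, net_b: nx.DiGraph) -> nx.DiGraph:
    """Union of two condition networks with membership annotations.

    Nodes and edges carry ``membership`` in {"A", "B", "both"} relative
    to the argument order; edge attributes of shared edges are taken from
    the first network (scores are per condition and kept per membership).
    """
    out = nx.DiGraph()
    for label, net in (("A", net_a), ("B", net_b)):
        for node, attrs in net.nodes(data=True):
            if node in out:
                out.nodes[node]["membership"] = "both"
                out.nodes[node]["is_regulator"] = (
                    out.nodes[node].get("is_regulator", False)
                    or attrs.get("is_regulator", False)
                )
            else:
                out.add_node(node, membership=label, **attrs)
        for u, v, attrs in net.edges(data=True):
            if out.has_edge(u, v):
                out.edges[u, v]["membership"] = "both"
            else:
                out.add_edge(u, v, membership=label, **attrs)
    return out
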