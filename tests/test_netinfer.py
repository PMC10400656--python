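import itertools

import mpmath
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosnet.netinfer import (
    DEPHOS,
    PHOS,
    UNDETERMINED,
    BDeuParams,
    CandidatePair,
    assign_sign,
    bdeu_score,
    combine_networks,
    concordance,
    find_candidates,
    infer_condition_network,
    select_parent_set,
)

# ---------------------------------------------------------------------------
# independent oracles


def concordance_oracle(r, p, lapse):
    """Brute-force loop over comparable transitions."""
    matches = total = 0
    T = len(r)
    for t in range(T):
        s = t - lapse
        if s < 0:
            continue
        total += 1
        if r[s] == p[t]:
            matches += 1
    return matches / total if total else 0.0


def sign_oracle(r, p, lapse):
    same = opp = 0
    for t in range(len(r)):
        s = t - lapse
        if s < 0:
            continue
        if r[s] != 0 and p[t] != 0:
            if r[s] == p[t]:
                same += 1
            else:
                opp += 1
    if same > opp:
        return PHOS
    if opp > same:
        return DEPHOS
    return UNDETERMINED


def bdeu_oracle(target, parents, alpha, variant="as_printed", dps=60):
    """Direct arbitrary-precision evaluation of the scoring formula."""
    mpmath.mp.dps = dps
    r_i = 3
    q_i = r_i ** len(parents)
    T = target.shape[1]
    max_lapse = max(lp for _, lp in parents)
    counts = {}
    for rep in range(target.shape[0]):
        for t in range(max_lapse, T):
            j = 0
            for levels, lapse in parents:
                j = j * r_i + int(levels[rep, t - lapse])
            k = int(target[rep, t])
            counts[(j, k)] = counts.get((j, k), 0) + 1
    a = mpmath.mpf(alpha)
    a_j = a / q_i
    a_jk = a / (r_i * q_i)
    inner = a_j if variant == "as_printed" else a_jk
    total = mpmath.mpf(0)
    for j in range(q_i):
        n_j = sum(counts.get((j, k), 0) for k in range(r_i))
        total += mpmath.log(mpmath.gamma(a_j) / mpmath.gamma(n_j + a_j))
        for k in range(r_i):
            n_jk = counts.get((j, k), 0)
            total += mpmath.log(mpmath.gamma(n_jk + inner) / mpmath.gamma(a_jk))
    return float(total)


def random_levels(rng, n_rep, n_time):
    return rng.integers(0, 3, size=(n_rep, n_time)).astype(np.int8)


# ---------------------------------------------------------------------------


class TestConcordance:
    def test_identical_series_full_concordance_at_lapse_zero(self, rng):
        d = rng.integers(-1, 2, 8)
        assert concordance(d, d, 0) == 1.0

    def test_everywhere_disagreeing_series(self):
        r = np.array([1, -1, 1, -1])
        p = np.array([-1, 1, -1, 1])
        assert concordance(r, p, 0) == 0.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            T = rng.integers(2, 12)
            r = rng.integers(-1, 2, T)
            p = rng.integers(-1, 2, T)
            for lapse in (0, 1):
                assert concordance(r, p, lapse) == pytest.approx(
                    concordance_oracle(r, p, lapse)
                )

    def test_strictly_greater_than_half_retained(self):
        # 3 of 5 transitions agree -> 0.6 retained; 2 of 4 -> 0.5 dropped
        deltas = pd.DataFrame(
            [[1, 1, 1, 0, 0], [1, 1, 1, 1, 1]],
            index=pd.MultiIndex.from_tuples(
                [("R1", 1, "S", 1), ("T1", 1, "S", 1)]
            ),
        )
        cands = find_candidates(deltas, [("R1", 1, "S", 1)], lapses=(0,))
        assert any(c.target == ("T1", 1, "S", 1) and c.concordance == 0.6
                   for c in cands)
        deltas4 = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 1, 1]],
            index=pd.MultiIndex.from_tuples(
                [("R1", 1, "S", 1), ("T1", 1, "S", 1)]
            ),
        )
        cands4 = find_candidates(deltas4, [("R1", 1, "S", 1)], lapses=(0,))
        assert not any(c.target == ("T1", 1, "S", 1) for c in cands4)

    def test_same_protein_pairs_excluded(self):
        deltas = pd.DataFrame(
            [[1, 1, 1], [1, 1, 1]],
            index=pd.MultiIndex.from_tuples([("R1", 1, "S", 1), ("R1", 9, "T", 1)]),
        )
        cands = find_candidates(deltas, [("R1", 1, "S", 1)])
        assert cands == []

    def test_no_regulators_warns_and_returns_empty(self, caplog):
        deltas = pd.DataFrame(
            [[1, 0, 1]], index=pd.MultiIndex.from_tuples([("T1", 1, "S", 1)])
        )
        with caplog.at_level("WARNING"):
            assert find_candidates(deltas, []) == []
        assert any("no regulator" in r.message for r in caplog.records)


class TestBDeuScore:
    @pytest.mark.parametrize("variant", ["as_printed", "standard"])
    def test_matches_high_precision_oracle(self, rng, variant):
        params = BDeuParams(formula_variant=variant)
        for _ in range(40):
            n_rep = int(rng.integers(1, 5))
            n_time = int(rng.integers(2, 7))
            n_par = int(rng.integers(1, 3))
            target = random_levels(rng, n_rep, n_time)
            parents = [
                (random_levels(rng, n_rep, n_time), int(rng.integers(0, 2)))
                for _ in range(n_par)
            ]
            got = bdeu_score(target, parents, params)
            want = bdeu_oracle(target, parents, params.alpha, variant)
            assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_to_data_vector_permutation(self, rng):
        target = random_levels(rng, 4, 6)
        parent = random_levels(rng, 4, 6)
        s1 = bdeu_score(target, [(parent, 0)])
        perm = rng.permutation(4)
        s2 = bdeu_score(target[perm], [(parent[perm], 0)])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_invariant_to_consistent_parent_relabeling(self, rng):
        target = random_levels(rng, 3, 5)
        parent = random_levels(rng, 3, 5)
        relabel = np.array([2, 0, 1], dtype=np.int8)  # permute parent level names
        s1 = bdeu_score(target, [(parent, 0)])
        s2 = bdeu_score(target, [(relabel[parent], 0)])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_empty_data_vector_set_errors(self):
        target = np.zeros((2, 1), dtype=np.int8)
        with pytest.raises(ValueError):
            bdeu_score(target, [(target.copy(), 1)])


class TestSelectParentSet:
    def _oracle(self, target, cands, levels_of, params, max_parents=2):
        """Exhaustive enumeration with the same tie-break rules."""
        sets = [(c,) for c in cands]
        if max_parents >= 2:
            sets += [
                p for p in itertools.combinations(cands, 2)
                if p[0].regulator != p[1].regulator
            ]
        best = None
        for ps in sets:
            score = bdeu_score(
                levels_of(target), [(levels_of(c.regulator), c.lapse) for c in ps],
                params,
            )
            key = (
                -round(score, 6),
                len(ps),
                -sum(c.concordance for c in ps) / len(ps),
                tuple(sorted((c.regulator, c.lapse) for c in ps)),
            )
            if best is None or key < best[0]:
                best = (key, ps, score)
        return best[1], best[2]

    def test_single_candidate_selected(self, rng):
        levels = {"T": random_levels(rng, 2, 5), "R": random_levels(rng, 2, 5)}
        cand = CandidatePair("R", "T", 0, 0.8)
        best = select_parent_set("T", [cand], levels.__getitem__)
        assert best is not None and best[0] == (cand,)

    def test_no_candidates_returns_none(self):
        assert select_parent_set("T", [], lambda s: None) is None

    def test_matches_exhaustive_enumeration(self, rng):
        params = BDeuParams()
        for _ in range(30):
            n_cand = int(rng.integers(1, 7))
            names = [f"R{i}" for i in range(n_cand)]
            levels = {"T": random_levels(rng, 3, 6)}
            cands = []
            for nm in names:
                levels[nm] = random_levels(rng, 3, 6)
                cands.append(
                    CandidatePair(nm, "T", int(rng.integers(0, 2)),
                                  float(rng.uniform(0.5, 1.0)))
                )
            got = select_parent_set("T", cands, levels.__getitem__, params)
            want = self._oracle("T", cands, levels.__getitem__, params)
            assert got[1] == pytest.approx(want[1], rel=1e-12)
            assert {c.regulator for c in got[0]} == {c.regulator for c in want[0]}

    def test_deterministic_true_parent_beats_noise(self, rng):
        """A parent with a noiseless deterministic level mapping outranks
        parents unrelated to the target."""
        T = 8
        parent = np.tile(np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=np.int8), (3, 1))
        target = parent.copy()  # deterministic identity mapping
        levels = {"T": target, "TRUE": parent}
        cands = [CandidatePair("TRUE", "T", 0, 1.0)]
        for i in range(3):
            levels[f"N{i}"] = random_levels(rng, 3, T)
            cands.append(CandidatePair(f"N{i}", "T", 0, 0.6))
        best = select_parent_set("T", cands, levels.__getitem__)
        assert [c.regulator for c in best[0]] == ["TRUE"]


class TestAssignSign:
    def test_identical_nonzero_series_is_phosphorylation(self):
        d = np.array([1, -1, 1, 0])
        assert assign_sign(d, d, 0) == PHOS

    def test_negated_series_is_dephosphorylation(self):
        d = np.array([1, -1, 1, 0])
        assert assign_sign(d, -d, 0) == DEPHOS

    def test_tie_is_undetermined(self):
        r = np.array([1, 1, 0])
        p = np.array([1, -1, 0])
        assert assign_sign(r, p, 0) == UNDETERMINED

    def test_no_joint_events_is_undetermined(self):
        assert assign_sign(np.array([1, 0]), np.array([0, 1]), 0) == UNDETERMINED

    def test_matches_brute_force_and_antisymmetry(self, rng):
        swap = {PHOS: DEPHOS, DEPHOS: PHOS, UNDETERMINED: UNDETERMINED}
        for _ in range(100):
            T = int(rng.integers(2, 12))
            r = rng.integers(-1, 2, T)
            p = rng.integers(-1, 2, T)
            for lapse in (0, 1):
                got = assign_sign(r, p, lapse)
                assert got == sign_oracle(r, p, lapse)
                assert assign_sign(-r, p, lapse) == swap[got]


class TestInferConditionNetwork:
    def _keys(self, names):
        return [(n, 101, "S", 1) for n in names]

    def test_no_candidates_gives_nodes_without_edges(self, rng):
        sites = self._keys(["R1", "T1"])
        deltas = pd.DataFrame(
            [[1, -1, 1, -1], [-1, 1, -1, 1]],
            index=pd.MultiIndex.from_tuples(sites),
        )
        levels = {s: random_levels(rng, 2, 5) for s in sites}
        # perfectly anti-concordant at lapse 0 and non-concordant at lapse 1
        g = infer_condition_network(deltas, levels, [sites[0]], "control",
                                    lapses=(0,))
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_non_regulator_sites_never_gain_out_edges(self, rng):
        sites = self._keys(["R1", "T1", "T2"])
        deltas = pd.DataFrame(
            [[1, 0, -1, 0], [1, 0, -1, 0], [1, 0, -1, 0]],
            index=pd.MultiIndex.from_tuples(sites),
        )
        levels = {s: random_levels(rng, 2, 5) for s in sites}
        g = infer_condition_network(deltas, levels, [sites[0]], "control")
        for u, v in g.edges():
            assert u == sites[0]

    def test_noiseless_two_regulator_fixture_recovers_truth(self):
        # R1 drives T1..T4 (identity), R2 drives T5..T8 (identity);
        # patterns chosen so cross-concordance stays at 0.5
        r1 = np.array([1, 0, -1, 0, 1, 0, -1, 0])
        r2 = np.array([0, 1, 0, -1, 0, 1, 0, -1])
        sites = self._keys(["R1", "R2"] + [f"T{i}" for i in range(1, 9)])
        rows = [r1, r2] + [r1] * 4 + [r2] * 4
        deltas = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(sites))
        lv1 = np.tile((r1 > 0).astype(np.int8), (3, 1))
        lv2 = np.tile((r2 > 0).astype(np.int8), (3, 1))
        levels = dict(zip(sites, [lv1, lv2] + [lv1] * 4 + [lv2] * 4))
        g = infer_condition_network(deltas, levels, sites[:2], "control",
                                    lapses=(0,))
        want = {(sites[0], s) for s in sites[2:6]} | {(sites[1], s) for s in sites[6:]}
        assert set(g.edges()) == want
        assert all(d["sign"] == PHOS for _, _, d in g.edges(data=True))


class TestCombineNetworks:
    def _net(self, edges, nodes=()):
        g = nx.DiGraph()
        for n in nodes:
            g.add_node(n, is_regulator=False)
        for u, v in edges:
            g.add_edge(u, v, sign=PHOS, lapse=0, score=-1.0)
            g.nodes[u]["is_regulator"] = True
            g.nodes[v].setdefault("is_regulator", False)
        return g

    def test_identical_networks_all_both(self):
        g = self._net([("a", "b"), ("a", "c")])
        combined = combine_networks(g, g.copy())
        assert all(d["membership"] == "both" for _, d in combined.nodes(data=True))
        assert all(d["membership"] == "both" for *_, d in combined.edges(data=True))

    def test_disjoint_networks_keep_sides(self):
        combined = combine_networks(
            self._net([("a", "b")]), self._net([("c", "d")])
        )
        assert combined.nodes["a"]["membership"] == "A"
        assert combined.nodes["d"]["membership"] == "B"
        assert combined.edges["a", "b"]["membership"] == "A"

    def test_partial_overlap_membership_counts(self):
        net_a = self._net([("a", "b"), ("a", "c")])
        net_b = self._net([("a", "b"), ("a", "d")])
        combined = combine_networks(net_a, net_b)
        members = [d["membership"] for *_, d in combined.edges(data=True)]
        assert sorted(members) == ["A", "B", "both"]
        assert combined.number_of_edges() == 3  # no edges dropped
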