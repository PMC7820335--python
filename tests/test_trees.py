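"""Local trees: distances, NJ recovery, quartet topologies, weighting."""

import io
import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode

from intromap import (
    majority_species_topology,
    monophyly_fraction,
    nj_tree,
    pairwise_distances,
    quartet_topology,
    topology_weights,
)
from intromap.trees import TreeError

from conftest import build_matrix


def read_newick(s):
    return TreeNode.read(io.StringIO(s))


# -- independent oracles -----------------------------------------------------


def bipartitions(tree, ref_leaf):
    """Non-trivial splits as frozensets of the side not containing ref_leaf."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref_leaf in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return out


def same_topology(t1, t2):
    ref = next(t1.tips()).name
    return bipartitions(t1, ref) == bipartitions(t2, ref)


def random_tree(rng, leaves):
    """Random binary topology with uniform(0.1, 1) branch lengths."""
    nodes = [TreeNode(name=x, length=float(rng.uniform(0.1, 1.0))) for x in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def additive_matrix(tree):
    dm = tree.tip_tip_distances()
    return SkbioDM(dm.data, ids=list(dm.ids))


def oracle_quartet_via_shear(tree, p1, p2, p3, o):
    """Prune-based read-off of the induced quartet topology."""
    sub = tree.copy().shear([p1, p2, p3, o])
    sub.prune()
    pairings = {0: (p1, p2), 1: (p2, p3), 2: (p2, o)}
    for idx, (a, b) in pairings.items():
        for node in sub.traverse(include_self=False):
            if node.is_tip():
                continue
            side = {t.name for t in node.tips()}
            comp = {p1, p2, p3, o} - side
            if side == {a, b} or comp == {a, b}:
                if (node.length or 0.0) > 1e-12:
                    return idx
                return None
    return None


# -- distances ---------------------------------------------------------------


class TestDistances:
    def test_identical_haplotypes_zero(self):
        gm = build_matrix([[0, 0], [1, 1]], ploidy=[1, 1], samples=["a", "b"])
        dm = pairwise_distances(gm)
        assert dm["a|0", "b|0"] == 0.0

    def test_three_in_hundred(self):
        codes = np.zeros((100, 2), dtype=np.int16)
        codes[:3, 1] = 1
        gm = build_matrix(codes, ploidy=[1, 1], samples=["a", "b"])
        dm = pairwise_distances(gm, model="raw")
        assert dm["a|0", "b|0"] == pytest.approx(0.03)

    def test_jc_correction_value(self):
        codes = np.zeros((100, 2), dtype=np.int16)
        codes[:3, 1] = 1
        gm = build_matrix(codes, ploidy=[1, 1], samples=["a", "b"])
        dm = pairwise_distances(gm, model="jc")
        # independent evaluation of the Jukes-Cantor map at p = 0.03
        expect = -0.75 * math.log(1 - 4 * 0.03 / 3)
        assert dm["a|0", "b|0"] == pytest.approx(expect, abs=1e-12)
        assert round(expect, 4) == 0.0306

    def test_pairwise_deletion(self):
        codes = np.array([[0, 1], [0, -1], [1, 1], [0, 0]], dtype=np.int16)
        gm = build_matrix(codes, ploidy=[1, 1], samples=["a", "b"])
        dm = pairwise_distances(gm)
        assert dm["a|0", "b|0"] == pytest.approx(1 / 3)

    def test_no_co_called_site_is_error(self):
        codes = np.array([[0, -1], [-1, 1]], dtype=np.int16)
        gm = build_matrix(codes, ploidy=[1, 1], samples=["a", "b"])
        with pytest.raises(TreeError, match="co-called"):
            pairwise_distances(gm)


# -- neighbor joining --------------------------------------------------------


class TestNeighborJoining:
    def test_additive_recovery_eight_leaves(self):
        rng = np.random.default_rng(10)
        leaves = [f"t{i}" for i in range(8)]
        tree = random_tree(rng, leaves)
        rec = nj_tree(additive_matrix(tree))
        assert same_topology(tree, rec)

    def test_four_leaf_matches_least_squares(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree = random_tree(rng, ["a", "b", "c", "d"])
            dm = additive_matrix(tree)
            rec = nj_tree(dm)
            # brute-force least squares over the three quartet topologies
            pairs = list(itertools.combinations(range(4), 2))
            ids = list(dm.ids)
            y = np.array([dm[ids[i], ids[j]] for i, j in pairs])
            best, best_resid = None, None
            for k, (x, y2) in enumerate([(0, 1), (0, 2), (0, 3)]):
                group = {x, y2}
                # design: 4 terminal branches + 1 internal
                X = np.zeros((6, 5))
                for r, (i, j) in enumerate(pairs):
                    X[r, i] = 1
                    X[r, j] = 1
                    if ({i, j} != group) and ({i, j} != {0, 1, 2, 3} - group):
                        X[r, 4] = 1
                resid = np.linalg.lstsq(X, y, rcond=None)[1]
                resid = float(resid[0]) if len(resid) else 0.0
                if best_resid is None or resid < best_resid - 1e-12:
                    best, best_resid = group, resid
            sides = bipartitions(rec, ids[0])
            rec_pair = next(iter(sides)) if sides else None
            rec_group = {ids.index(n) for n in rec_pair} if rec_pair else None
            if rec_group is not None and 0 not in rec_group:
                rec_group = {0, 1, 2, 3} - rec_group
            assert rec_group == best or rec_group == {0, 1, 2, 3} - best

    def test_identical_haplotypes_are_siblings(self):
        codes = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 0], [1, 1, 0, 0]], dtype=np.int16
        )
        gm = build_matrix(codes, ploidy=[1, 1, 1, 1], samples=list("abcd"))
        tree = nj_tree(pairwise_distances(gm))
        a = tree.find("a|0")
        b = tree.find("b|0")
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0


# -- quartet topologies ------------------------------------------------------


SPECIES_NEWICK = "(((p1:1,p2:1):1,p3:2):1,o:3);"
INTRO_NEWICK = "(((p2:1,p3:1):1,p1:2):1,o:3);"
STAR_NEWICK = "((p1:1,p2:1):0.0,(p3:1,o:1):0.0);"


class TestQuartetTopology:
    def test_species_read_off(self):
        tree = read_newick(SPECIES_NEWICK)
        m = {"P1": "p1", "P2": "p2", "P3": "p3", "O": "o"}
        assert quartet_topology(tree, m) == 0

    def test_introgression_read_off(self):
        tree = read_newick(INTRO_NEWICK)
        m = {"P1": "p1", "P2": "p2", "P3": "p3", "O": "o"}
        assert quartet_topology(tree, m) == 1

    def test_star_is_unresolved(self):
        tree = read_newick(STAR_NEWICK)
        m = {"P1": "p1", "P2": "p2", "P3": "p3", "O": "o"}
        assert quartet_topology(tree, m) is None


# two haplotypes per group; one P2 haplotype (p2b) nests inside the P3 clade
MIXED_NEWICK = (
    "(((p1a:0.1,p1b:0.1):0.5,(p2a:0.1,p2x:0.0):0.5):0.5,"
    "((p3a:0.1,p3b:0.1):0.5,(o1:0.1,o2:0.1):0.5):0.5);"
)


def sorted_two_per_group_tree():
    return read_newick(
        "(((p1a:0.1,p1b:0.1):0.4,(p2a:0.1,p2b:0.1):0.4):0.3,"
        "((p3a:0.1,p3b:0.1):0.4,(o1:0.1,o2:0.1):0.4):0.3);"
    )


GROUPS2 = {
    "P1": ["p1a", "p1b"],
    "P2": ["p2a", "p2b"],
    "P3": ["p3a", "p3b"],
    "O": ["o1", "o2"],
}


class TestTopologyWeights:
    def test_reciprocally_monophyletic_species_weight_one(self):
        qw = topology_weights(sorted_two_per_group_tree(), GROUPS2, method="exact")
        assert qw.n_combinations == 16
        assert qw.w_species == 1.0
        assert qw.n_unresolved == 0

    def test_exact_matches_shear_enumeration_oracle(self):
        tree = read_newick(
            "(((p1a:0.1,p1b:0.1):0.4,(p2a:0.1,o_extra:0.1):0.4):0.3,"
            "((p3a:0.1,(p3b:0.1,p2b:0.1):0.2):0.4,(o1:0.1,o2:0.1):0.4):0.3);"
        )
        groups = {
            "P1": ["p1a", "p1b"],
            "P2": ["p2a", "p2b"],
            "P3": ["p3a", "p3b"],
            "O": ["o1", "o2"],
        }
        qw = topology_weights(tree, groups, method="exact")
        counts = [0, 0, 0]
        unresolved = 0
        for combo in itertools.product(*(groups[r] for r in ("P1", "P2", "P3", "O"))):
            t = oracle_quartet_via_shear(tree, *combo)
            if t is None:
                unresolved += 1
            else:
                counts[t] += 1
        total = sum(counts)
        assert qw.n_unresolved == unresolved
        assert qw.weights == pytest.approx(tuple(c / total for c in counts))

    def test_weights_sum_to_one_and_partition(self):
        qw = topology_weights(read_newick(MIXED_NEWICK), {
            "P1": ["p1a", "p1b"],
            "P2": ["p2a", "p2x"],
            "P3": ["p3a", "p3b"],
            "O": ["o1", "o2"],
        }, method="exact")
        assert qw.n_combinations == 16
        assert sum(qw.weights) == pytest.approx(1.0)
        assert qw.n_unresolved + qw.n_decisive == 16

    def test_monte_carlo_within_three_se(self):
        tree = read_newick(
            "(((p1a:0.1,p1b:0.1):0.4,(p2a:0.1,p2b:0.3):0.4):0.3,"
            "((p3a:0.1,(p3b:0.1,p2c:0.1):0.2):0.4,(o1:0.1,o2:0.1):0.4):0.3);"
        )
        groups = {
            "P1": ["p1a", "p1b"],
            "P2": ["p2a", "p2b", "p2c"],
            "P3": ["p3a", "p3b"],
            "O": ["o1", "o2"],
        }
        exact = topology_weights(tree, groups, method="exact")
        mc = topology_weights(tree, groups, method="monte_carlo", draws=10_000, seed=1)
        for we, wm in zip(exact.weights, mc.weights):
            se = math.sqrt(max(we * (1 - we), 1e-9) / 10_000)
            assert abs(we - wm) <= 3 * se + 1e-9

    def test_leaf_permutation_invariance(self):
        qw1 = topology_weights(read_newick(MIXED_NEWICK), {
            "P1": ["p1b", "p1a"],
            "P2": ["p2x", "p2a"],
            "P3": ["p3b", "p3a"],
            "O": ["o2", "o1"],
        }, method="exact")
        qw2 = topology_weights(read_newick(MIXED_NEWICK), {
            "P1": ["p1a", "p1b"],
            "P2": ["p2a", "p2x"],
            "P3": ["p3a", "p3b"],
            "O": ["o1", "o2"],
        }, method="exact")
        assert qw1.weights == qw2.weights

    def test_missing_group_raises(self):
        with pytest.raises(TreeError):
            topology_weights(sorted_two_per_group_tree(), {
                "P1": ["p1a"], "P2": ["p2a"], "P3": ["p3a"], "O": [],
            })


class TestMonophyly:
    def test_all_concordant(self):
        t_mono = sorted_two_per_group_tree()
        assert monophyly_fraction([t_mono, t_mono], GROUPS2, ["P1", "P2"]) == 1.0
        assert monophyly_fraction([t_mono], GROUPS2, ["P3"]) == 1.0

    def test_two_of_four(self):
        t_mono = sorted_two_per_group_tree()
        # swap p2b and p3a so P1 u P2 is no longer a clade
        t_swapped = read_newick(
            "(((p1a:0.1,p1b:0.1):0.4,(p2a:0.1,p3a:0.1):0.4):0.3,"
            "((p2b:0.1,p3b:0.1):0.4,(o1:0.1,o2:0.1):0.4):0.3);"
        )
        frac = monophyly_fraction(
            [t_mono, t_mono, t_swapped, t_swapped], GROUPS2, ["P1", "P2"]
        )
        assert frac == 0.5


class TestMajorityTopology:
    def _qw(self, w):
        from intromap import QuartetTopologyWeights

        return QuartetTopologyWeights(w[0], w[1], w[2], 16, 0, "exact")

    def test_all_species(self):
        modal, fr = majority_species_topology([self._qw((1, 0, 0))] * 3)
        assert modal == 0 and fr == (1.0, 0.0, 0.0)

    def test_two_one_split(self):
        ws = [self._qw((0.9, 0.1, 0)), self._qw((0.8, 0.2, 0)), self._qw((0.1, 0.9, 0))]
        modal, fr = majority_species_topology(ws)
        assert modal == 0
        assert fr == pytest.approx((2 / 3, 1 / 3, 0.0))
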