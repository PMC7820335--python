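"""Local trees and quartet topology weighting.

Per-window trees are built by neighbor joining on pairwise-deletion
haplotype distances. Topology weighting decomposes a tree with several
haplotypes per group into the fraction of single-haplotype-per-group
quartets inducing each of the three unrooted topologies:

* ``species``       ((P1, P2), (P3, O)) - the genome-wide expectation,
* ``introgression`` ((P2, P3), (P1, O)) - the introgressed line groups with
  the donor,
* ``control``       ((P2, O), (P1, P3)) - the negative control.

A quartet's topology is read off through the four-point condition on
tip-to-tip path lengths: the pairing with the strictly smallest distance sum
wins, and ties (a zero-length internal branch) are counted as unresolved.
Unresolved quartets are excluded from the weight denominator and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .genotype import MISSING, GenotypeMatrix, PopulationMap

TOPOLOGY_NAMES = ("species", "introgression", "control")
UNRESOLVED = None

# distance assigned when a raw proportion is at/above Jukes-Cantor saturation
JC_SATURATION_DISTANCE = 5.0


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class QuartetTopologyWeights:
    """Topology weights over decisive single-haplotype-per-group quartets."""

    w_species: float
    w_introgression: float
    w_control: float
    n_combinations: int
    n_unresolved: int
    method: str  # "exact" or "monte_carlo(seed=..., draws=...)"

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_species, self.w_introgression, self.w_control)

    @property
    def n_decisive(self) -> int:
        return self.n_combinations - self.n_unresolved

    @property
    def argmax(self) -> int | None:
        w = self.weights
        if self.n_decisive == 0:
            return UNRESOLVED
        m = max(w)
        best = [i for i, v in enumerate(w) if v == m]
        return best[0] if len(best) == 1 else UNRESOLVED


# -- distances and NJ --------------------------------------------------------


def pairwise_distances(
    gm_window: GenotypeMatrix,
    model: str = "raw",
    columns: Sequence[int] | None = None,
    labels: Sequence[str] | None = None,
) -> SkbioDM:
    """Pairwise-deletion haplotype distances over a window.

    ``raw``: proportion of differing allele codes over co-called sites.
    ``jc``: Jukes-Cantor correction -(3/4) ln(1 - (4/3) p); saturated pairs
    (p >= 0.75) are set to a large configured distance with a warning.
    """
    codes = gm_window.codes
    if columns is not None:
        codes = codes[:, np.asarray(columns, dtype=np.intp)]
    if labels is None:
        all_labels = gm_window.haplotype_labels()
        labels = (
            [all_labels[c] for c in columns] if columns is not None else all_labels
        )
    h = codes.shape[1]
    if h < 2:
        raise TreeError("need at least 2 haplotypes for distances")
    called = codes != MISSING
    # (sites, i, j) broadcast; windows are small enough for dense booleans
    co = called[:, :, None] & called[:, None, :]
    diff = (codes[:, :, None] != codes[:, None, :]) & co
    n_co = co.sum(axis=0)
    n_diff = diff.sum(axis=0)
    off = ~np.eye(h, dtype=bool)
    if np.any(n_co[off] == 0):
        i, j = np.argwhere((n_co == 0) & off)[0]
        raise TreeError(
            f"haplotypes {labels[i]!r} and {labels[j]!r} share no co-called site"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_co > 0, n_diff / np.maximum(n_co, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    if model == "raw":
        d = p
    elif model == "jc":
        d = np.empty_like(p)
        sat = p >= 0.75
        if np.any(sat & off):
            warnings.warn(
                "Jukes-Cantor saturation (p >= 0.75); using fixed large distance"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            d[~sat] = -0.75 * np.log1p(-(4.0 / 3.0) * p[~sat])
        d[sat] = JC_SATURATION_DISTANCE
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown distance model {model!r}")
    d = (d + d.T) / 2.0  # exact symmetry for the skbio constructor
    return SkbioDM(d, ids=list(labels))


def nj_tree(dm: SkbioDM) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero."""
    if len(dm.ids) < 3:
        raise TreeError("neighbor joining needs at least 3 labels")
    tree = _skbio_nj(dm)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _tip_distance_matrix(tree: TreeNode) -> tuple[np.ndarray, dict[str, int]]:
    dm = tree.tip_tip_distances()
    index = {name: i for i, name in enumerate(dm.ids)}
    return dm.data, index


def _pairing_sums(
    d: np.ndarray, i1: np.ndarray, i2: np.ndarray, i3: np.ndarray, i4: np.ndarray
):
    """Distance sums of the three pairings for quartets (P1,P2,P3,O)."""
    s_species = d[i1, i2] + d[i3, i4]  # P1P2 | P3O
    s_intro = d[i2, i3] + d[i1, i4]  # P2P3 | P1O
    s_control = d[i2, i4] + d[i1, i3]  # P2O | P1P3
    return np.stack([s_species, s_intro, s_control], axis=-1)


def quartet_topology(
    tree: TreeNode, one_per_group: Mapping[str, str], atol: float = 1e-12
) -> int | None:
    """Induced quartet topology index for one haplotype per role.

    Returns 0 (species), 1 (introgression), 2 (control), or None when the
    induced quartet is a star (zero-length internal branch).
    """
    d, index = _tip_distance_matrix(tree)
    try:
        idx = [index[one_per_group[r]] for r in ("P1", "P2", "P3", "O")]
    except KeyError as exc:
        raise TreeError(f"haplotype {exc} is not a leaf of the tree")
    sums = _pairing_sums(d, *(np.asarray([i]) for i in idx))[0]
    order = np.argsort(sums)
    if sums[order[1]] - sums[order[0]] <= atol:
        return UNRESOLVED
    return int(order[0])


def topology_weights(
    tree: TreeNode,
    group_leaves: Mapping[str, Sequence[str]],
    method: str = "exact",
    draws: int = 10_000,
    seed: int | None = None,
    atol: float = 1e-12,
) -> QuartetTopologyWeights:
    """Topology weights over single-haplotype-per-group quartet combinations.

    *group_leaves* maps each role P1, P2, P3, O to its leaf labels. ``exact``
    enumerates the full product of group sizes; ``monte_carlo`` samples
    combinations with replacement under *seed*.
    """
    d, index = _tip_distance_matrix(tree)
    groups = []
    for r in ("P1", "P2", "P3", "O"):
        leaves = list(group_leaves.get(r, ()))
        if not leaves:
            raise TreeError(f"role {r} has no leaves in the tree")
        try:
            groups.append(np.asarray([index[x] for x in leaves], dtype=np.intp))
        except KeyError as exc:
            raise TreeError(f"leaf {exc} absent from tree")

    if method == "exact":
        i1, i2, i3, i4 = np.meshgrid(*groups, indexing="ij")
        sums = _pairing_sums(d, i1.ravel(), i2.ravel(), i3.ravel(), i4.ravel())
        method_tag = "exact"
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        picks = [g[rng.integers(0, len(g), size=draws)] for g in groups]
        sums = _pairing_sums(d, *picks)
        method_tag = f"monte_carlo(seed={seed}, draws={draws})"
    else:
        raise ValueError(f"unknown method {method!r}")

    order = np.sort(sums, axis=-1)
    decisive = (order[:, 1] - order[:, 0]) > atol
    winner = np.argmin(sums, axis=-1)
    n_comb = sums.shape[0]
    n_dec = int(decisive.sum())
    if n_dec == 0:
        w = (0.0, 0.0, 0.0)
    else:
        w = tuple(float(((winner == k) & decisive).sum()) / n_dec for k in range(3))
    return QuartetTopologyWeights(
        w_species=w[0],
        w_introgression=w[1],
        w_control=w[2],
        n_combinations=n_comb,
        n_unresolved=n_comb - n_dec,
        method=method_tag,
    )


def group_leaves_from_popmap(
    gm: GenotypeMatrix, pm: PopulationMap, exclude_pools: bool = True
) -> dict[str, list[str]]:
    """Role -> haplotype leaf labels, optionally dropping pooled samples."""
    labels = gm.haplotype_labels()
    out: dict[str, list[str]] = {}
    for role in ("P1", "P2", "P3", "O"):
        group = pm.role_group(role)
        leaves: list[str] = []
        for s in pm.samples_of(group):
            if s not in gm.samples:
                continue
            if exclude_pools and gm.ploidy[gm.samples.index(s)] > 2:
                continue
            leaves.extend(labels[c] for c in gm.haplotype_columns(s))
        out[role] = leaves
    return out


# -- tree-set summaries ------------------------------------------------------


def monophyly_fraction(
    trees: Sequence[TreeNode],
    group_leaves: Mapping[str, Sequence[str]],
    groups: Sequence[str],
) -> float:
    """Fraction of trees in which the union of *groups*' leaves is a clade.

    Clades are judged unrooted: some bipartition of the tree must separate
    exactly that union from everything else.
    """
    target = frozenset(x for g in groups for x in group_leaves[g])
    if not trees:
        raise ValueError("empty tree list")
    hits = 0
    for tree in trees:
        all_tips = frozenset(t.name for t in tree.tips())
        if not target <= all_tips:
            raise TreeError("group leaves missing from a tree")
        complement = all_tips - target
        if not complement or len(target) == 1:
            hits += 1
            continue
        found = False
        for node in tree.traverse(include_self=False):
            if node.is_tip():
                side = frozenset((node.name,))
            else:
                side = frozenset(t.name for t in node.tips())
            if side == target or side == complement:
                found = True
                break
        hits += found
    return hits / len(trees)


def majority_species_topology(
    weights_per_window: Sequence[QuartetTopologyWeights],
) -> tuple[int, tuple[float, float, float]]:
    """Modal per-window argmax topology and the fraction of windows per topology.

    Windows whose weights are tied or fully unresolved do not vote; fractions
    are over voting windows.
    """
    votes = [w.argmax for w in weights_per_window if w.argmax is not UNRESOLVED]
    if not votes:
        raise TreeError("no window with decisive weights")
    counts = [votes.count(k) for k in range(3)]
    fractions = tuple(c / len(votes) for c in counts)
    return int(np.argmax(counts)), fractions


def weights_to_tsv(
    windows_weights: Sequence[tuple[object, QuartetTopologyWeights | None]], path: str
) -> None:
    """Per-window weights TSV; windows without a tree serialize as NA."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tw_species\tw_introgression\tw_control\t"
            "n_combinations\tn_unresolved\tmethod\n"
        )
        for w, qw in windows_weights:
            if qw is None:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\tNA\tNA\tNA\t0\t0\tNA\n")
            else:
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{qw.w_species:.6g}\t"
                    f"{qw.w_introgression:.6g}\t{qw.w_control:.6g}\t"
                    f"{qw.n_combinations}\t{qw.n_unresolved}\t{qw.method}\n"
                )


def scan_trees(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    windows: Sequence,
    model: str = "raw",
    method: str = "exact",
    draws: int = 10_000,
    seed: int | None = None,
    min_sites: int = 1,
    exclude_pools: bool = True,
) -> list[tuple[object, QuartetTopologyWeights | None, TreeNode | None]]:
    """Build an NJ tree per window and weight its quartet topologies.

    Windows with fewer than *min_sites* usable sites, or where some
    haplotype pair shares no co-called site, yield ``None`` entries.
    """
    from .genotype import window_site_index

    group_leaves = group_leaves_from_popmap(gm, pm, exclude_pools=exclude_pools)
    cols: list[int] = []
    labels = gm.haplotype_labels()
    keep = {x for leaves in group_leaves.values() for x in leaves}
    for c, lab in enumerate(labels):
        if lab in keep:
            cols.append(c)
    col_labels = [labels[c] for c in cols]

    out = []
    for w in windows:
        sl = window_site_index(gm, w)
        if sl.stop - sl.start < min_sites:
            out.append((w, None, None))
            continue
        sub = gm.take(np.arange(sl.start, sl.stop))
        try:
            dm = pairwise_distances(sub, model=model, columns=cols, labels=col_labels)
            tree = nj_tree(dm)
            qw = topology_weights(
                tree, group_leaves, method=method, draws=draws, seed=seed
            )
        except TreeError:
            out.append((w, None, None))
            continue
        out.append((w, qw, tree))
    return out
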