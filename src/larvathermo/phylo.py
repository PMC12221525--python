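"""Phylogenetic comparative post-processing of preference traits.

Species-level traits (Tp_opt, the upper bound of Tp_breadth) are mapped onto
a dated phylogeny to ask how temperature preference evolved: maximum-
likelihood ancestral states under Brownian motion, per-lineage shifts (tip
value minus the inferred state of its parent node), and a phylogenetically
corrected ANOVA whose null F distribution comes from traits simulated under
Brownian motion on the tree.

Under Brownian motion with a flat prior on the root state, the joint
distribution of node states is Gaussian with precision proportional to the
tree's graph Laplacian weighted by inverse branch lengths; the ML ancestral
states are therefore the solution of a sparse linear system conditioning
internal nodes on the tips, and their variances scale the inverse of the
internal-block Laplacian by the ML rate estimate.
"""

from __future__ import annotations

import dendropy
import numpy as np
from scipy import stats


class DatedTree:
    """A dated phylogeny (branch lengths in Myr) with convenience indexing.

    Wraps a dendropy tree; warns (via ``is_ultrametric``) rather than fails
    when branch lengths are not ultrametric, since empirical dated trees
    carry rounding error.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        # stable node ordering: tips first (leaf order), then internals
        self._tips = list(tree.leaf_node_iter())
        self._internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        self.nodes = self._tips + self._internals
        self._index = {id(nd): i for i, nd in enumerate(self.nodes)}

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def n_internal(self) -> int:
        return len(self._internals)

    def is_ultrametric(self, rel_tol: float = 1e-3) -> bool:
        depths = [leaf.distance_from_root() for leaf in self._tips]
        span = max(depths) - min(depths)
        return span <= rel_tol * max(depths)

    def edges(self):
        """(parent_index, child_index, length) triples."""
        out = []
        for nd in self.tree.preorder_node_iter():
            for ch in nd.child_nodes():
                if ch.edge.length is None:
                    raise ValueError("tree has a branch without a length")
                out.append((self._index[id(nd)], self._index[id(ch)],
                            float(ch.edge.length)))
        return out

    def tip_covariance(self) -> np.ndarray:
        """BM covariance among tips: shared root-to-MRCA path lengths."""
        pdm = self.tree.phylogenetic_distance_matrix()
        n = self.n_tips
        depth = {id(nd): nd.distance_from_root() for nd in self.tree}
        C = np.empty((n, n))
        for i, a in enumerate(self._tips):
            C[i, i] = depth[id(a)]
            for j in range(i + 1, n):
                b = self._tips[j]
                mrca = pdm.mrca(a.taxon, b.taxon)
                C[i, j] = C[j, i] = depth[id(mrca)]
        return C

    def to_newick(self, node_values: dict | None = None) -> str:
        """Newick string; optionally annotate internal nodes with values as
        node comments."""
        if node_values:
            for nd in self._internals:
                i = self._index[id(nd)]
                if i in node_values:
                    nd.annotations["state"] = f"{node_values[i]:.4g}"
        return self.tree.as_string(schema="newick",
                                   suppress_annotations=node_values is None).strip()


def read_newick(text: str) -> DatedTree:
    """Parse a Newick tree with branch lengths (string or file-like)."""
    if hasattr(text, "read"):
        text = text.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return DatedTree(tree)


def read_trait_csv(path_or_buf) -> dict:
    """Tip-label -> trait value from a two-column (tip,value) CSV."""
    import pandas as pd
    df = pd.read_csv(path_or_buf, header=None, names=["tip", "value"],
                     comment="#", skip_blank_lines=True)
    # tolerate an optional header row
    try:
        float(df.iloc[0]["value"])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    return {str(r.tip): float(r.value) for r in df.itertuples()}


def _trait_vector(tree: DatedTree, traits: dict) -> np.ndarray:
    missing = [t for t in tree.tip_labels if t not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing}")
    return np.array([float(traits[t]) for t in tree.tip_labels])


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------

def _laplacian(tree: DatedTree) -> np.ndarray:
    n = len(tree.nodes)
    L = np.zeros((n, n))
    for (p, c, ln) in tree.edges():
        if ln <= 0:
            ln = 1e-12  # zero-length branch: effectively fuse the nodes
        w = 1.0 / ln
        L[p, p] += w
        L[c, c] += w
        L[p, c] -= w
        L[c, p] -= w
    return L


def bm_ancestral_states(tree: DatedTree, traits: dict):
    """ML ancestral states (+ variances) under Brownian motion.

    Solves the inverse-branch-length-weighted Laplacian system conditioning
    internal nodes on the observed tips — algebraically the generalized
    least-squares estimate with the BM tree covariance, and identical to the
    classic re-rooting construction.  Variances are the conditional
    variances scaled by the ML rate estimate.  Returns ``(states, variances)``
    as dicts keyed by internal-node index into ``tree.nodes`` (the root is
    the first internal index, ``tree.n_tips``).
    """
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    x = _trait_vector(tree, traits)
    n_tip, n_int = tree.n_tips, tree.n_internal
    L = _laplacian(tree)
    L_ii = L[n_tip:, n_tip:]
    L_it = L[n_tip:, :n_tip]
    try:
        states = np.linalg.solve(L_ii, -L_it @ x)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular tree covariance: {exc}") from exc
    sigma2 = bm_rate(tree, traits, method="ml")
    cond_var = sigma2 * np.diag(np.linalg.inv(L_ii))
    idx = range(n_tip, n_tip + n_int)
    return ({i: float(s) for i, s in zip(idx, states)},
            {i: float(v) for i, v in zip(idx, cond_var)})


def bm_rate(tree: DatedTree, traits: dict, method: str = "reml") -> float:
    """Brownian-motion rate estimate from the tips.

    GLS with the tree covariance: the root state is the GLS mean and the
    rate is the quadratic form divided by n (ML) or n-1 (REML, the default
    for simulation nulls)."""
    x = _trait_vector(tree, traits)
    C = tree.tip_covariance()
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(x))
    mu = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    q = (x - mu) @ Cinv @ (x - mu)
    denom = len(x) if method == "ml" else len(x) - 1
    return float(q / denom)


def lineage_shifts(tree: DatedTree, traits: dict, ancestral: dict | None = None) -> dict:
    """Signed per-tip shift: tip value minus its parent node's BM estimate.

    A large negative shift on a lineage marks a derived move toward cooler
    preference relative to the inferred ancestor."""
    if ancestral is None:
        ancestral, _ = bm_ancestral_states(tree, traits)
    shifts = {}
    for i, leaf in enumerate(tree._tips):
        parent = leaf.parent_node
        p_idx = tree._index[id(parent)]
        shifts[tree.tip_labels[i]] = float(traits[tree.tip_labels[i]] - ancestral[p_idx])
    return shifts


# ---------------------------------------------------------------------------
# Phylogenetically corrected ANOVA
# ---------------------------------------------------------------------------

def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in range(n_groups):
        vals = values[codes == g]
        ss_between += vals.size * (vals.mean() - grand) ** 2
        ss_within += np.sum((vals - vals.mean()) ** 2)
    df_b = n_groups - 1
    df_w = values.size - n_groups
    if df_w <= 0 or ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def phylo_anova(tree: DatedTree, groups: dict, traits: dict,
                n_sim: int = 1000, seed=None, rate_method: str = "reml"):
    """Simulation-based phylogenetically corrected one-way ANOVA.

    The observed F comes from a standard one-way ANOVA of tip traits across
    groups; the null distribution is built by simulating traits under
    Brownian motion on the tree (rate estimated from the data) and
    recomputing F for each simulated dataset.  Because close relatives are
    correlated under BM, this null is wider than the iid-ANOVA null, which
    is exactly the phylogenetic correction.  Returns ``(F, p)`` with the
    standard add-one Monte Carlo p-value.
    """
    x = _trait_vector(tree, traits)
    labels = [groups[t] for t in tree.tip_labels]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.array([uniq.index(l) for l in labels])
    f_obs = _anova_f(x, codes, len(uniq))
    if f_obs == 0.0:
        return 0.0, 1.0

    rng = np.random.default_rng(seed)
    sigma2 = bm_rate(tree, traits, method=rate_method)
    C = tree.tip_covariance()
    chol = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(len(x)))
    sims = chol @ rng.standard_normal((len(x), n_sim))
    count = 0
    for k in range(n_sim):
        if _anova_f(sims[:, k], codes, len(uniq)) >= f_obs:
            count += 1
    p = (count + 1) / (n_sim + 1)
    return float(f_obs), float(p)
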