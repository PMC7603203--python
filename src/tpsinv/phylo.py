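"""Reference-guided phylogenetic assignment of terpene synthases.

Desk-scale machinery for the third evidence stream of the inventory
pipeline: exact global pairwise alignment (Gotoh affine-gap dynamic
programming under BLOSUM62), percent-identity and p-distance computation,
neighbor joining with deterministic tie-breaking, nonparametric bootstrap
over alignment columns, and clade-membership labeling of a query against
reference proteins of known function (a query inherits a reference family's
label when it nests inside that family's clade with bootstrap support at or
above a threshold, 50 by default).

Trees are :class:`skbio.TreeNode` objects; internal nodes carry a
``support`` attribute in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from skbio import TreeNode

_NEG = float("-inf")
GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global-alignment parameters.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal
    gaps are penalized (true global alignment).  ``identity_denominator``
    selects the percent-identity convention: ``"trimmed"`` excludes terminal
    gap runs from the denominator, ``"full"`` counts every alignment column.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "trimmed"

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.identity_denominator not in ("trimmed", "full"):
            raise ValueError("identity_denominator must be 'trimmed' or 'full'")


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float


_MATRIX_CACHE: dict = {}


def _submatrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def align_global(a: str, b: str, params: Optional[AlignmentParams] = None) -> Alignment:
    """Optimal global alignment of two protein sequences (Gotoh algorithm).

    Dynamic programming is vectorized row-wise; the traceback breaks ties
    deterministically, preferring diagonal over up (gap in ``b``) over left
    (gap in ``a``).
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    mat = _submatrix(params.matrix)
    go, ge = params.gap_open, params.gap_extend
    m, n = len(a), len(b)
    sub = np.empty((m, n))
    for i, ra in enumerate(a):
        row = mat[ra]
        for j, rb in enumerate(b):
            sub[i, j] = row[rb]

    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # gap in b (vertical / "up")
    Y = np.full((m + 1, n + 1), _NEG)  # gap in a (horizontal / "left")
    M[0, 0] = 0.0
    j_idx = np.arange(1, n + 1)
    ge_ramp = np.arange(n + 1) * ge

    def fill_Y(i: int):
        # Y[i, j] = max_{k < j} M[i, k] - go - (j - 1 - k) * ge, vectorized
        # via a running maximum of M[i, k] + k * ge.
        with np.errstate(invalid="ignore"):
            t = M[i, :n] + ge_ramp[:n]
        run = np.maximum.accumulate(t)
        Y[i, 1:] = run - go - (j_idx - 1) * ge
        Y[i, 0] = _NEG

    fill_Y(0)
    for i in range(1, m + 1):
        X[i] = np.maximum(M[i - 1] - go, X[i - 1] - ge)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:n]
        M[i, 0] = _NEG
        fill_Y(i)

    # Traceback with diagonal > up > left preference on ties.
    i, j = m, n
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i, j], -" MXY".index(s)))
    out_a: list[str] = []
    out_b: list[str] = []
    score = {"M": M, "X": X, "Y": Y}[state][m, n]
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            cands = ((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y"))
            best = max(c[0] for c in cands)
            state = next(s for v, s in cands if v == best)
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            prev_m, prev_x = M[i - 1, j] - go, X[i - 1, j] - ge
            i -= 1
            state = "M" if prev_m >= prev_x else "X"
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            prev_m, prev_y = M[i, j - 1] - go, Y[i, j - 1] - ge
            j -= 1
            state = "M" if prev_m >= prev_y else "Y"
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))


def pairwise_identity(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Percent amino-acid identity of the optimal global alignment.

    Under the default ``trimmed`` convention, leading and trailing gap-run
    columns are excluded from the denominator; ``full`` divides by every
    alignment column.
    """
    params = params or AlignmentParams()
    aln = align_global(a, b, params)
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    lo, hi = 0, len(cols)
    if params.identity_denominator == "trimmed":
        while lo < hi and GAP in cols[lo]:
            lo += 1
        while hi > lo and GAP in cols[hi - 1]:
            hi -= 1
    window = cols[lo:hi]
    if not window:
        return 0.0
    matches = sum(1 for x, y in window if x == y and x != GAP)
    return 100.0 * matches / len(window)


# ---------------------------------------------------------------------------
# Neighbor joining


def _as_matrix(dm, ids=None) -> tuple[list, np.ndarray]:
    try:  # pandas DataFrame
        import pandas as pd

        if isinstance(dm, pd.DataFrame):
            return list(dm.index), dm.to_numpy(dtype=float)
    except ImportError:  # pragma: no cover
        pass
    arr = np.asarray(dm, dtype=float)
    if ids is None:
        ids = [f"t{k}" for k in range(arr.shape[0])]
    return list(ids), arr


def nj_tree(dm, ids: Optional[Sequence[str]] = None) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q criterion are broken by the lowest (row, column) index
    pair in the current agglomeration order; negative branch lengths are
    clamped to zero with the deficit transferred to the sister edge.  The
    returned tree is unrooted, represented with a trifurcating root.
    """
    names, d = _as_matrix(dm, ids)
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes = [TreeNode(name=nm) for nm in names]
    d = d.copy()
    while len(nodes) > 3:
        r = d.shape[0]
        totals = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.empty((r - 1, r - 1))
        d2[: r - 2, : r - 2] = d[np.ix_(keep, keep)]
        d2[-1, : r - 2] = dnew[keep]
        d2[: r - 2, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form star resolution of the final three lineages
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.length = float(max(ln, 0.0))
        root.append(node)
    return root


def tree_bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of an unrooted tree as canonical frozensets.

    Each internal edge is represented by the side of its split that does not
    contain the lexicographically smallest leaf.
    """
    leaves = sorted(t.name for t in tree.tips())
    all_set = frozenset(leaves)
    anchor = leaves[0]
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = all_set - side
        parts.add(side)
    return parts


# ---------------------------------------------------------------------------
# Bootstrap


def _char_matrix(msa: Sequence[tuple]) -> tuple[list, np.ndarray]:
    names = [nm for nm, _ in msa]
    lens = {len(s) for _, s in msa}
    if len(lens) != 1:
        raise ValueError("bootstrap requires aligned sequences of equal length")
    arr = np.frombuffer("".join(s for _, s in msa).encode(), dtype="S1").reshape(len(names), -1)
    return names, arr


def _p_distance_matrix(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    gap = arr == GAP.encode()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            d[i, j] = d[j, i] = 1.0 if m == 0 else float((arr[i, ok] != arr[j, ok]).mean())
    return d


def bootstrap_support(
    msa: Mapping[str, str] | Sequence[tuple],
    n_replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Supports are the percentage of replicate NJ trees (on p-distances of
    column-resampled alignments) containing each internal bipartition of the
    tree built on the full alignment.  Input order does not matter: taxa are
    canonicalized to sorted-name order and one RNG stream is seeded once.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    items = sorted(msa.items()) if isinstance(msa, Mapping) else sorted(msa)
    names, arr = _char_matrix(items)
    ncols = arr.shape[1]
    tree = nj_tree(_p_distance_matrix(arr), ids=names)
    targets = {}
    for node in tree.non_tips(include_self=False):
        node.support = None
    anchor = sorted(names)[0]
    all_set = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(names) - 2:
            key = side if anchor not in side else all_set - side
            targets.setdefault(key, []).append(node)
    counts = {key: 0 for key in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = nj_tree(_p_distance_matrix(arr[:, cols]), ids=names)
        parts = tree_bipartitions(rep)
        for key in counts:
            if key in parts:
                counts[key] += 1
    for key, nodes in targets.items():
        support = 100.0 * counts[key] / n_replicates
        for node in nodes:
            node.support = support
    return tree


def to_newick(tree: TreeNode) -> str:
    """Newick with branch lengths and integer supports as internal labels."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            base = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            support = getattr(node, "support", None)
            label = "" if support is None else str(int(round(support)))
            base = f"({inner}){label}"
        if node.length is not None:
            base += f":{node.length:g}"
        return base

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# Progressive alignment (guide order from a preliminary NJ tree)


def _nw_linear(colscore: np.ndarray, gap: float) -> tuple[list, list]:
    """Linear-gap global DP over a precomputed column-score matrix.

    Returns index paths into the two profiles (None marks a gap column).
    """
    m, n = colscore.shape
    H = np.zeros((m + 1, n + 1))
    H[0, :] = -gap * np.arange(n + 1)
    H[:, 0] = -gap * np.arange(m + 1)
    jg = np.arange(1, n + 1) * gap
    for i in range(1, m + 1):
        diag = H[i - 1, :n] + colscore[i - 1]
        up = H[i - 1, 1:] - gap
        best = np.maximum(diag, up)
        # horizontal (left) moves folded in via a running maximum:
        # H[i, j] = max_{k <= j} (best_k - (j - k) * gap), plus the all-gap row
        run = np.maximum.accumulate(best + jg)
        H[i, 1:] = np.maximum(run - jg, -gap * i - jg)
    pa: list = []
    pb: list = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + colscore[i - 1, j - 1]):
            pa.append(i - 1)
            pb.append(j - 1)
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] - gap):
            pa.append(i - 1)
            pb.append(None)
            i -= 1
        else:
            pa.append(None)
            pb.append(j - 1)
            j -= 1
    return pa[::-1], pb[::-1]


_AA_ORDER = "ACDEFGHIKLMNPQRSTVWYBZX*"


def _profile_score_matrix(p1: Sequence[str], p2: Sequence[str], matrix: str) -> np.ndarray:
    mat = _submatrix(matrix)
    k = len(_AA_ORDER)
    B = np.full((k + 1, k + 1), -4.0)
    for x in range(k):
        for y in range(k):
            try:
                B[x, y] = mat[_AA_ORDER[x]][_AA_ORDER[y]]
            except (KeyError, IndexError):  # pragma: no cover
                B[x, y] = -1.0
    B[k, :] = B[:, k] = -4.0
    B[k, k] = 0.0
    lut = {ch: i for i, ch in enumerate(_AA_ORDER)}
    lut[GAP] = k

    def encode(seq: str) -> np.ndarray:
        return np.array([lut.get(c, lut["X"]) for c in seq], dtype=int)

    e1 = [encode(s) for s in p1]
    e2 = [encode(s) for s in p2]
    total = np.zeros((len(e1[0]), len(e2[0])))
    for s in e1:
        for t in e2:
            total += B[s[:, None], t[None, :]]
    return total / (len(e1) * len(e2))


def _merge_profiles(p1: dict, p2: dict, matrix: str, gap: float = 8.0) -> dict:
    s1, s2 = list(p1.values()), list(p2.values())
    pa, pb = _nw_linear(_profile_score_matrix(s1, s2, matrix), gap)
    out = {}
    for name, seq in p1.items():
        out[name] = "".join(seq[i] if i is not None else GAP for i in pa)
    for name, seq in p2.items():
        out[name] = "".join(seq[j] if j is not None else GAP for j in pb)
    return out


def progressive_msa(seqs: Mapping[str, str], params: Optional[AlignmentParams] = None) -> dict:
    """Progressive multiple alignment guided by a preliminary NJ tree.

    Pairwise p-distances (1 - identity/100) define the guide tree; profiles
    are merged bottom-up in its topology with sum-of-pairs BLOSUM scoring
    and a flat per-column gap cost.  Adequate for the desk-scale reference
    panels this package targets, not a general MSA engine.
    """
    params = params or AlignmentParams()
    names = sorted(seqs)
    if len(names) == 1:
        return {names[0]: seqs[names[0]]}
    if len(names) == 2:
        aln = align_global(seqs[names[0]], seqs[names[1]], params)
        return {names[0]: aln.aligned_a, names[1]: aln.aligned_b}
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ident = pairwise_identity(seqs[names[i]], seqs[names[j]], params)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    guide = nj_tree(d, ids=names)

    def build(node: TreeNode) -> dict:
        if node.is_tip():
            return {node.name: seqs[node.name]}
        profiles = [build(child) for child in node.children]
        merged = profiles[0]
        for nxt in profiles[1:]:
            merged = _merge_profiles(merged, nxt, params.matrix)
        return merged

    return build(guide)


# ---------------------------------------------------------------------------
# Clade-membership assignment


def assign_by_reference(
    query_name: str,
    query_seq: str,
    references: Mapping[str, str],
    labels: Mapping[str, str],
    support_threshold: float = 50.0,
    n_replicates: int = 100,
    seed: int = 0,
    params: Optional[AlignmentParams] = None,
) -> str:
    """Label a query by the reference clade it nests within.

    Builds a bootstrap NJ tree on the query plus labeled references and
    walks from the query tip towards the root; the first ancestor clade
    containing references yields its label when all of its references agree
    and its bipartition support meets ``support_threshold``.  A clade of
    mixed labels, or exhaustion of supported ancestors, yields
    ``"unassigned"``.
    """
    label_set = {labels[nm] for nm in references}
    if len(label_set) < 2:
        raise ValueError("assignment needs references from at least 2 labels")
    if query_name in references:
        raise ValueError("query name collides with a reference name")
    seqs = dict(references)
    seqs[query_name] = query_seq
    if len({len(s) for s in seqs.values()}) == 1:
        msa = seqs
    else:
        msa = progressive_msa(seqs, params)
    tree = bootstrap_support(msa, n_replicates=n_replicates, seed=seed)
    tip = next(t for t in tree.tips() if t.name == query_name)
    for anc in tip.ancestors():
        if anc.is_root():
            break
        clade = {t.name for t in anc.tips()} - {query_name}
        refs_in = clade & set(references)
        if not refs_in:
            continue
        clade_labels = {labels[nm] for nm in refs_in}
        if len(clade_labels) > 1:
            return "unassigned"
        support = getattr(anc, "support", None)
        if support is None or support >= support_threshold:
            return clade_labels.pop()
        return "unassigned"
    # The query hangs directly off the (trifurcating) root: fall back to the
    # nearest pure-labeled root subtree that meets the support threshold.
    items = sorted(msa.items()) if isinstance(msa, Mapping) else sorted(msa)
    names, arr = _char_matrix(items)
    dmat = _p_distance_matrix(arr)
    idx = {nm: k for k, nm in enumerate(names)}
    qi = idx[query_name]
    best = None
    root = tree.root()
    for child in root.children:
        clade = {t.name for t in child.tips()} - {query_name}
        refs_in = clade & set(references)
        if not refs_in or query_name in {t.name for t in child.tips()}:
            continue
        clade_labels = {labels[nm] for nm in refs_in}
        if len(clade_labels) > 1:
            continue
        support = getattr(child, "support", None)
        if support is not None and support < support_threshold:
            continue
        mean_d = float(np.mean([dmat[qi, idx[nm]] for nm in refs_in]))
        if best is None or mean_d < best[0]:
            best = (mean_d, clade_labels.pop())
    return best[1] if best is not None else "unassigned"
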