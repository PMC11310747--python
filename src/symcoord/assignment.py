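"""Atom assignment: map atoms to symmetry-equivalent counterparts or to
model atoms.

Two methods:

* Hungarian (:func:`assign_minimal_cost`): minimum total squared distance
  over element-preserving bijections, solved with
  ``scipy.optimize.linear_sum_assignment``.  Cross-element matches are
  forbidden by an effectively infinite cost.
* Graph matching (:func:`assign_by_graph`): element- and
  adjacency-preserving bijection for heavily distorted structures whose
  distance-based matching would fail; among automorphic alternatives the
  one with the lowest summed squared distance after a trial rigid
  superposition wins, remaining ties broken by lexicographic atom order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import AssignmentError
from .operations import SymmetryOperation, apply_operation

_FORBIDDEN = 1e12  # cost barring cross-element matches


@dataclass
class AssignmentMap:
    """A bijection from source atoms to target atoms.

    ``permutation[i]`` is the target index matched to source atom i;
    ``total_cost`` is the summed squared distance (A^2) of matched pairs.
    """

    permutation: np.ndarray
    total_cost: float
    method: str = "hungarian"

    def __post_init__(self):
        perm = np.asarray(self.permutation, dtype=int)
        n = len(perm)
        if sorted(perm.tolist()) != list(range(n)):
            raise AssignmentError("permutation is not a bijection on 0..N-1")
        self.permutation = perm

    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(len(self.permutation))
        return inv


def _element_check(a, b) -> None:
    ca, cb = Counter(a), Counter(b)
    if ca != cb:
        diff = {
            el: (ca.get(el, 0), cb.get(el, 0))
            for el in sorted(set(ca) | set(cb))
            if ca.get(el, 0) != cb.get(el, 0)
        }
        raise AssignmentError(
            f"element multisets differ (source, target counts): {diff}"
        )


def assign_minimal_cost(
    source: np.ndarray, target: np.ndarray, elements, target_elements=None
) -> AssignmentMap:
    """Optimal element-preserving bijection minimizing summed squared
    distance between ``source`` and permuted ``target`` positions.

    ``elements`` labels the source atoms; ``target_elements`` defaults to the
    same list (symmetry self-assignment).
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if len(S) == 0:
        raise AssignmentError("cannot assign zero atoms")
    if S.shape != T.shape:
        raise AssignmentError(
            f"atom counts differ: {S.shape[0]} vs {T.shape[0]}"
        )
    elements = list(elements)
    target_el = list(target_elements) if target_elements is not None else elements
    _element_check(elements, target_el)
    cost = ((S[:, None, :] - T[None, :, :]) ** 2).sum(axis=2)
    el = np.asarray(elements)
    tel = np.asarray(target_el)
    cost[el[:, None] != tel[None, :]] = _FORBIDDEN
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())
    if total >= _FORBIDDEN:
        raise AssignmentError("no element-preserving assignment exists")
    perm = np.empty(len(S), dtype=int)
    perm[rows] = cols
    return AssignmentMap(perm, total, "hungarian")


def symmetry_permutation(
    coords: np.ndarray, elements, op: SymmetryOperation
) -> AssignmentMap:
    """Assignment of each atom to its symmetry image under ``op``:
    transformed atom i is matched to original atom ``permutation[i]``."""
    return assign_minimal_cost(apply_operation(op, coords), coords, elements)


def assign_by_graph(query, model, max_isomorphisms: int = 10000) -> AssignmentMap:
    """Element- and adjacency-preserving bijection query -> model.

    Both molecules must carry bond graphs isomorphic as element-labeled
    graphs.  ``permutation[i]`` is the model index of query atom i.
    """
    import networkx as nx

    gq = _to_graph(query)
    gm = _to_graph(model)
    if gq.number_of_nodes() != gm.number_of_nodes():
        raise AssignmentError(
            f"atom counts differ: query {gq.number_of_nodes()} vs "
            f"model {gm.number_of_nodes()}"
        )
    _element_check(
        [d["element"] for _, d in gq.nodes(data=True)],
        [d["element"] for _, d in gm.nodes(data=True)],
    )
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        gq, gm, node_match=lambda a, b: a["element"] == b["element"]
    )
    qc = np.asarray(query.coords, dtype=float)
    mc = np.asarray(model.coords, dtype=float)
    best = None
    n_found = 0
    for mapping in matcher.isomorphisms_iter():
        n_found += 1
        perm = np.array([mapping[i] for i in range(len(qc))])
        cost = _superposed_cost(qc, mc[perm])
        key = (round(cost, 9), tuple(perm.tolist()))
        if best is None or key < best[0]:
            best = (key, perm, cost)
        if n_found >= max_isomorphisms:
            break
    if best is None:
        sig_q = _degree_signature(gq)
        sig_m = _degree_signature(gm)
        raise AssignmentError(
            "molecular graphs are not isomorphic as element-labeled graphs; "
            f"(element, degree) signatures query={sig_q} model={sig_m}"
        )
    return AssignmentMap(best[1], best[2], "graph")


def _to_graph(mol):
    import networkx as nx

    if mol.bonds is None:
        raise AssignmentError(
            f"molecule {getattr(mol, 'id', '?')} carries no bond graph"
        )
    g = nx.Graph()
    for i, el in enumerate(mol.elements):
        g.add_node(i, element=el)
    for bond in mol.bonds:
        g.add_edge(int(bond[0]), int(bond[1]))
    return g


def _degree_signature(g) -> dict:
    sig = Counter(
        (d["element"], g.degree(n)) for n, d in g.nodes(data=True)
    )
    return dict(sorted(sig.items()))


def _superposed_cost(q: np.ndarray, m: np.ndarray) -> float:
    """Residual sum of squares after optimal rigid superposition (Kabsch)."""
    qc = q - q.mean(axis=0)
    mc = m - m.mean(axis=0)
    H = qc.T @ mc
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    rss = (qc**2).sum() + (mc**2).sum() - 2.0 * (s[0] + s[1] + d * s[2])
    return float(max(rss, 0.0))
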