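"""Shared test utilities: independent oracles and random model generators.

The dense-network oracle solves the full resistor network as a linear
system (nodal analysis) — completely independent of the recursive
series-parallel reduction it checks.  The random-model generator
constructs closed-loop models whose steady state is *known by
construction*: it picks a target operating point on both cardiac
curves first and then chooses the blood volume that puts the
conservation plane through it.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from steadycirc import (
    CardiacCurve,
    CirculationModel,
    Compartment,
    Leaf,
    Parallel,
    ResistanceNetwork,
    Series,
    conservation_coefficients,
)


# --------------------------------------------------------------------------
# Dense linear-network oracle for G coefficients


def dense_g_coefficients(net: ResistanceNetwork):
    """Node pressures of the full resistor network at unit total flow.

    Returns (G, fractions) like ``derive_g_coefficients`` but computed
    by building every internal node explicitly and solving the nodal
    conductance system with the atrium grounded at 0.
    """
    counter = itertools.count(2)  # 0 = circuit entry, 1 = atrium (ground)
    edges = []  # (u, v, R)
    cap_node = {}
    cap_exit = {}

    def emit(node, u, v):
        if isinstance(node, Leaf):
            cid = node.compartment
            c = next(counter)
            cap_node[cid] = c
            cap_exit[cid] = v
            edges.append((u, c, net.arterial[cid]))
            edges.append((c, v, net.venous[cid]))
        elif isinstance(node, Series):
            nodes = [u] + [next(counter) for _ in node.children[:-1]] + [v]
            for child, a, b in zip(node.children, nodes[:-1], nodes[1:]):
                emit(child, a, b)
        elif isinstance(node, Parallel):
            for b in node.branches:
                emit(b, u, v)
        else:  # pragma: no cover
            raise TypeError(node)

    emit(net.root, 0, 1)
    n = next(counter)
    L = np.zeros((n, n))
    for u, v, r in edges:
        g = 1.0 / r
        L[u, u] += g
        L[v, v] += g
        L[u, v] -= g
        L[v, u] -= g
    rhs = np.zeros(n)
    rhs[0] = 1.0  # unit cardiac output injected at the arterial entry
    rhs[1] = -1.0
    keep = [i for i in range(n) if i != 1]  # ground the atrium
    P = np.zeros(n)
    P[keep] = np.linalg.solve(L[np.ix_(keep, keep)], rhs[keep])
    G = {cid: P[c] for cid, c in cap_node.items()}
    fractions = {
        cid: (P[c] - P[cap_exit[cid]]) / net.venous[cid]
        for cid, c in cap_node.items()
    }
    return G, fractions


def random_sp_tree(rng, ids, depth=0):
    """Random series-parallel topology over the given compartment ids."""
    if len(ids) == 1:
        return Leaf(ids[0])
    if depth >= 3:
        return Series(tuple(Leaf(i) for i in ids))
    k = min(len(ids), int(rng.integers(2, 4)))
    cuts = sorted(rng.choice(np.arange(1, len(ids)), size=k - 1, replace=False))
    groups = np.split(np.asarray(ids, dtype=object), cuts)
    children = tuple(random_sp_tree(rng, list(g), depth + 1) for g in groups)
    return Series(children) if rng.random() < 0.5 else Parallel(children)


def random_network(rng, n_comps=None):
    n = n_comps or int(rng.integers(2, 7))
    ids = [f"c{i}" for i in range(n)]
    tree = random_sp_tree(rng, ids)
    arterial = {i: float(rng.uniform(0.2, 40.0)) for i in ids}
    venous = {i: float(rng.uniform(0.2, 40.0)) for i in ids}
    return ResistanceNetwork(tree, arterial, venous)


# --------------------------------------------------------------------------
# Random closed-loop models with a known steady state


def random_model(rng, balanced=True):
    """A random valid circulation model plus its constructed solution.

    Returns ``(model, Q_star)`` where ``Q_star`` is the exact cardiac
    output: the blood volume is chosen so that the conservation plane
    passes through the point where both cardiac curves deliver
    ``Q_star``.
    """
    Pe_R = float(rng.uniform(-6.0, 0.0))
    Pe_L = Pe_R if balanced else float(rng.uniform(-6.0, 0.0))
    K_R = float(rng.uniform(8.0, 20.0))
    K_L = K_R if balanced else K_R * float(rng.uniform(0.8, 1.25))
    right = CardiacCurve(K=K_R, alpha=float(rng.uniform(20, 80)),
                         beta=float(rng.uniform(0.3, 1.0)), P_ext=Pe_R)
    left = CardiacCurve(K=K_L, alpha=float(rng.uniform(10, 40)),
                        beta=float(rng.uniform(0.2, 0.6)), P_ext=Pe_L)

    def make_comps(circuit, count, prefix):
        return [
            Compartment(
                id=f"{prefix}{i}", circuit=circuit,
                C=float(rng.uniform(0.01, 0.15)),
                V0n=float(rng.uniform(0.05, 1.0)),
                P_ext=float(rng.uniform(-5.0, 1.0)),
                RA=float(rng.uniform(0.3, 40.0)),
                RV=float(rng.uniform(0.3, 8.0)),
            )
            for i in range(count)
        ]

    pul = make_comps("pulmonary", int(rng.integers(1, 4)), "pul")
    sys_ = make_comps("systemic", int(rng.integers(1, 5)), "sys")
    comps = (
        Compartment("ra", "right_atrium", C=float(rng.uniform(0.005, 0.03)),
                    V0n=0.1, P_ext=Pe_R),
        *pul,
        Compartment("la", "left_atrium", C=float(rng.uniform(0.005, 0.03)),
                    V0n=0.1, P_ext=Pe_L),
        *sys_,
    )
    pul_tree = random_sp_tree(rng, [c.id for c in pul])
    sys_tree = random_sp_tree(rng, [c.id for c in sys_])

    # pick a target operating point, then choose BV to realize it
    Z_star = float(rng.uniform(0.15, 0.85))
    Q_star = Z_star * min(K_R, K_L)
    P_R_star = right.inverse(Q_star)
    P_L_star = left.inverse(Q_star)
    V0 = 0.4
    proto = CirculationModel(
        right_heart=right, left_heart=left, compartments=comps,
        pulmonary_topology=pul_tree, systemic_topology=sys_tree,
        BV=V0 + sum(c.V0n for c in comps) + 5.0, V0=V0,
    )
    rf = conservation_coefficients(proto)
    D_star = rf.CS * P_R_star + rf.CP * P_L_star + rf.CR * Q_star
    BV = D_star - sum(c.C * c.P_ext for c in comps) + V0 + sum(c.V0n for c in comps)
    if BV <= V0:  # implausible draw; try again with fresh parameters
        return random_model(rng, balanced=balanced)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # dBV <= 0 draws are fine here
        model = CirculationModel(
            right_heart=right, left_heart=left, compartments=comps,
            pulmonary_topology=pul_tree, systemic_topology=sys_tree,
            BV=BV, V0=V0,
        )
    return model, Q_star
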