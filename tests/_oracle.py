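"""Independent brute-force evaluation of the flow-network indices.

Deliberately written apart from the production code: a dense numpy matrix
is filled cell by cell, marginals are row/column sums, and every index is
a literal double loop over matrix entries.  Used as the reference the
production implementation must match to 1e-9 relative.
"""

import math

import numpy as np


def network_to_matrix(network, include_self_loops=True):
    ids = sorted({c.id for c in network.compartments})
    index = {cid: k for k, cid in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for f in network.flows:
        if f.source == f.target and not include_self_loops:
            continue
        mat[index[f.source], index[f.target]] += abs(f.best)
    return mat


def brute_force_indices(mat, log_base=2.0):
    """TST, AMI, A, flow-diversity C and throughflow-diversity C by loops."""
    n = mat.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += mat[i, j]
    row = [sum(mat[i, j] for j in range(n)) for i in range(n)]
    col = [sum(mat[i, j] for i in range(n)) for j in range(n)]

    def log(x):
        return math.log(x, log_base)

    ami = 0.0
    asc = 0.0
    cap_flow = 0.0
    for i in range(n):
        for j in range(n):
            t = mat[i, j]
            if t > 0.0:
                ami += (t / total) * log(t * total / (row[i] * col[j]))
                asc += t * log(t * total / (row[i] * col[j]))
                cap_flow -= t * log(t / total)
    cap_through = 0.0
    for i in range(n):
        if row[i] > 0.0:
            cap_through -= row[i] * log(row[i] / total)
    return {
        "tst": total,
        "ami": ami,
        "ascendency": asc,
        "capacity_flow": cap_flow,
        "capacity_throughflow": cap_through,
    }
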