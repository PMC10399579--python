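"""Independent brute-force ssGSEA oracle used only by the tests.

Implements the statistic literally: hand-rolled tie-aware ranking, an
explicit walk down the ranked gene list, and accumulation of the in-set and
out-of-set ECDFs at every position.  Shares no code with the package's
vectorized closed form.
"""

from __future__ import annotations


def oracle_ranks(values, tie_method="average"):
    """Ranks 1..N, largest value -> N; ties averaged or by ascending index."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    ranks = [0.0] * n
    if tie_method == "ordinal":
        for pos, i in enumerate(order, start=1):
            ranks[i] = float(pos)
        return ranks
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_es(values, member_indices, alpha=0.25, tie_method="average"):
    """Positional-loop enrichment score for one cell and one gene set."""
    n = len(values)
    members = set(int(i) for i in member_indices)
    assert 0 < len(members) < n
    ranks = oracle_ranks(values, tie_method)
    # walk order: decreasing rank, ties by ascending gene index
    walk = sorted(range(n), key=lambda g: (-ranks[g], g))
    w_total = sum(ranks[g] ** alpha for g in members)
    n_out = n - len(members)
    p_in = 0.0
    p_out = 0.0
    es = 0.0
    for g in walk:
        if g in members:
            p_in += ranks[g] ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def oracle_score_matrix(matrix_genes_by_cells, sets_indices, alpha=0.25, tie_method="average"):
    """cells x sets score table via the positional loop, cell by cell."""
    n_genes = len(matrix_genes_by_cells)
    n_cells = len(matrix_genes_by_cells[0])
    out = []
    for c in range(n_cells):
        col = [matrix_genes_by_cells[g][c] for g in range(n_genes)]
        out.append([oracle_es(col, idx, alpha, tie_method) for idx in sets_indices])
    return out
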