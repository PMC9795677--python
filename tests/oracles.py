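"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration rather than
calling the library's algorithms, so they can certify the dynamic-programming
and matching implementations on small instances.
"""

from itertools import permutations


def collapse_tandem_cells(cells):
    """Published collapse rule, re-implemented by direct set manipulation:
    where one gene hits a run of rank-consecutive partners, keep the
    lowest-rank hit; left side first, then right side."""
    for side in (0, 1):
        other = 1 - side
        by_gene = {}
        for c in cells:
            by_gene.setdefault(c[side], []).append(c)
        kept = []
        for gene in by_gene:
            hits = sorted(by_gene[gene], key=lambda c: c[other])
            kept.append(hits[0])
            for prev, cur in zip(hits, hits[1:]):
                if cur[other] - prev[other] > 1:
                    kept.append(cur)
        cells = sorted(set(kept))
    return cells


def _all_chains(cells, direction, gap):
    """Every monotone chain (including length-1) over the cells."""
    cells = sorted(cells)

    def successors(c):
        return [d for d in cells
                if 1 <= d[0] - c[0] <= gap and 1 <= (d[1] - c[1]) * direction <= gap]

    def rec(chain):
        yield list(chain)
        for d in successors(chain[-1]):
            chain.append(d)
            yield from rec(chain)
            chain.pop()

    for c in cells:
        yield from rec([c])


def brute_force_blocks(cells, min_anchors=4, max_rank_gap=25, allow_descending=True,
                       collapse=True):
    """Greedy extraction of maximal monotone chains by full enumeration.

    Returns [(direction, [(ra, rb), ...]), ...] in extraction order.  The
    selection key is: longest chain first, ascending preferred over
    descending, then lexicographically smallest (ra, rb) sequence.
    """
    remaining = collapse_tandem_cells(sorted(set(cells))) if collapse \
        else sorted(set(cells))
    out = []
    directions = (1, -1) if allow_descending else (1,)
    while len(remaining) >= min_anchors:
        best = None
        for direction in directions:
            for chain in _all_chains(remaining, direction, max_rank_gap):
                key = (-len(chain), 0 if direction == 1 else 1,
                       tuple(chain))
                if best is None or key < best[0]:
                    best = (key, chain, direction)
        if best is None or len(best[1]) < min_anchors:
            break
        out.append((best[2], best[1]))
        chosen = set(best[1])
        remaining = [c for c in remaining if c not in chosen]
    return out


def brute_force_matching(weights):
    """Maximum-weight one-to-one matching by trying every permutation.

    ``weights``: dict[(row, col)] -> positive weight.  Returns the set of
    matched (row, col) pairs of one optimal solution's positive-weight edges;
    the optimum is assumed unique in the instances this is used on.
    """
    rows = sorted({r for r, _ in weights})
    cols = sorted({c for _, c in weights})
    if len(rows) > len(cols):
        best = brute_force_matching({(c, r): w for (r, c), w in weights.items()})
        return {(r, c) for c, r in best}
    best_score, best_pairs = -1, set()
    for perm in permutations(cols, len(rows)):
        pairs = {(r, c) for r, c in zip(rows, perm) if (r, c) in weights}
        score = sum(weights[p] for p in pairs)
        if score > best_score:
            best_score, best_pairs = score, pairs
    return best_pairs
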