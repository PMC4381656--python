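"""Independent brute-force oracles for the feature definitions.

Each function recomputes a quantity by direct enumeration over every edge,
ordered domain-instance pair or neighbour, sharing no code with the
package implementations it is used to check.
"""

from collections import Counter


def brute_interaction_matrix(edges, domains_of):
    """Accumulate 1/(M·N) for every ordered domain-instance pair of every edge."""
    mass = {}
    for a, b in edges:
        s_a = list(Counter(domains_of[a]).elements())
        s_b = list(Counter(domains_of[b]).elements())
        if not s_a or not s_b:
            continue
        w = 1.0 / (len(s_a) * len(s_b))
        for alpha in s_a:
            for beta in s_b:
                key = tuple(sorted((alpha, beta)))
                mass[key] = mass.get(key, 0.0) + w
    return mass


def brute_edge_ddi(ratio_map, domains_a, domains_b):
    """Sum ratio values strictly above one over the edge's distinct pairs."""
    pairs = {tuple(sorted((x, y))) for x in domains_a for y in domains_b}
    return sum(r for p in pairs if (r := ratio_map.get(p, 0.0)) > 1.0)


def brute_dfs(cancer_count, noncancer_count, domains_a, domains_b, m, n):
    """Loop over every domain instance on both endpoints."""
    c = x = 0
    for d in list(domains_a) + list(domains_b):
        c += cancer_count.get(d, 0)
        x += noncancer_count.get(d, 0)
    return c / (m + n), x / (m + n)


def brute_cld(edges, cancer, a, b):
    """Neighbour fraction by scanning the full edge list."""
    neighbours = set()
    for u, v in edges:
        if u in (a, b):
            neighbours.add(v)
        if v in (a, b):
            neighbours.add(u)
    neighbours -= {a, b}
    if not neighbours:
        return 0.0
    return sum(1 for p in neighbours if p in cancer) / len(neighbours)


def brute_majority(vote_rows):
    """Per-position majority by explicit counting; vote_rows: list of tuples."""
    out = []
    for votes in vote_rows:
        ones = sum(1 for v in votes if v == 1)
        out.append(1 if ones > len(votes) - ones else 0)
    return out
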