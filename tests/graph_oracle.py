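"""Brute-force graph oracles (BFS path enumeration) for small graphs.

Independent of networkx-based production code: shortest paths are found
by exhaustive breadth-first search, betweenness by enumerating all
shortest paths between every ordered pair, clustering by triangle
counting over neighbor pairs.
"""

from itertools import combinations


def bfs_all_shortest_paths(adj, s, t):
    """All shortest s->t paths by BFS layer expansion; [] if unreachable."""
    if s == t:
        return [[s]]
    frontier = [[s]]
    seen = {s}
    while frontier:
        next_frontier = []
        found = []
        layer_nodes = set()
        for path in frontier:
            for nb in adj[path[-1]]:
                if nb in seen:
                    continue
                newp = path + [nb]
                if nb == t:
                    found.append(newp)
                else:
                    next_frontier.append(newp)
                    layer_nodes.add(nb)
        if found:
            return found
        seen |= layer_nodes
        frontier = next_frontier
    return []


def oracle_metrics(nodes, edges):
    """Path length, betweenness, closeness (Wasserman-Faust), clustering.

    Returns dict with 'apl' (mean shortest-path length over connected
    pairs), and per-node 'betweenness' (normalized by (n-1)(n-2)/2),
    'closeness', 'clustering'.
    """
    nodes = list(nodes)
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    dist = {}
    paths = {}
    for s, t in combinations(nodes, 2):
        ps = bfs_all_shortest_paths(adj, s, t)
        if ps:
            dist[(s, t)] = dist[(t, s)] = len(ps[0]) - 1
            paths[(s, t)] = ps

    connected = [d for d in dist.values()]
    apl = sum(connected) / len(connected) if connected else 0.0

    betweenness = {}
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    for v in nodes:
        score = 0.0
        for (s, t), ps in paths.items():
            through = sum(1 for p in ps if v in p[1:-1])
            score += through / len(ps)
        betweenness[v] = score / norm

    closeness = {}
    for v in nodes:
        reach = [dist[(v, u)] for u in nodes if u != v and (v, u) in dist]
        if not reach or sum(reach) == 0:
            closeness[v] = 0.0
        else:
            nr = len(reach)  # reachable nodes excluding v
            closeness[v] = (nr / sum(reach)) * (nr / (n - 1))

    clustering = {}
    for v in nodes:
        nbrs = list(adj[v])
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        clustering[v] = 2.0 * links / (k * (k - 1))

    return {
        "apl": apl,
        "betweenness": betweenness,
        "closeness": closeness,
        "clustering": clustering,
    }
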