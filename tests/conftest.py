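import numpy as np
import pytest

from cooccur import OTUTable, fixture_graphs


@pytest.fixture
def small_table():
    """3 OTUs x 4 samples with hand-checkable structure."""
    counts = np.array(
        [
            [6, 2, 0, 5],
            [4, 4, 3, 0],
            [0, 4, 7, 5],
        ]
    )
    return OTUTable(["OTU_A", "OTU_B", "OTU_C"], ["S1", "S2", "S3", "S4"], counts)


@pytest.fixture
def table_tsv(tmp_path):
    """Hand-written TSV fixture with a taxonomy column."""
    path = tmp_path / "table.tsv"
    path.write_text(
        "#OTU ID\tS1\tS2\ttaxonomy\n"
        "OTU_1\t10\t0\tBacteria;Proteobacteria;Escherichia\n"
        "OTU_2\t3\t5\tBacteria;Firmicutes;Streptococcus\n"
        "OTU_3\t0\t2\tBacteria;Firmicutes;Clostridium\n"
    )
    return path


@pytest.fixture(scope="session")
def graphs():
    return fixture_graphs()


def brute_force_transitivity(graph):
    """Independent oracle: enumerate node triples, count closed vs connected."""
    from itertools import combinations

    nodes = list(graph.nodes())
    triangles = 0
    connected_triples = 0
    for a, b, c in combinations(nodes, 3):
        edges = [graph.has_edge(a, b), graph.has_edge(a, c), graph.has_edge(b, c)]
        n_edges = sum(edges)
        if n_edges == 3:
            triangles += 1
            connected_triples += 3  # each vertex centers a triple
        elif n_edges == 2:
            connected_triples += 1
    if connected_triples == 0:
        return 0.0
    return 3.0 * triangles / connected_triples


def brute_force_betweenness(graph):
    """Independent oracle: hand-rolled BFS plus explicit shortest-path enumeration.

    For every unordered pair (s, t), credit each interior node v with the
    fraction of shortest s-t paths passing through it.
    """
    from collections import deque
    from itertools import combinations

    nodes = list(graph.nodes())
    adj = {v: set() for v in nodes}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)

    def bfs_dist(s):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        return dist

    def all_shortest_paths(s, t, dist):
        # walk backwards from t along strictly distance-decreasing edges
        paths = []

        def extend(path):
            head = path[-1]
            if head == s:
                paths.append(list(reversed(path)))
                return
            for w in adj[head]:
                if dist.get(w) == dist[head] - 1:
                    extend(path + [w])

        extend([t])
        return paths

    scores = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        paths = all_shortest_paths(s, t, dist)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    return scores
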