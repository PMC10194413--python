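"""Independent brute-force oracles for small digraphs.

Everything here is deliberately naive (adjacency-matrix Floyd-Warshall,
exhaustive DFS path/cycle enumeration, direct degree counting) and never
calls the package's graph code, so metric and contraction results can be
checked against a second, independent route.
"""

from __future__ import annotations

from itertools import permutations


def brute_roles(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, str]:
    """Node roles by direct in/out-degree inspection."""
    out = {}
    for v in nodes:
        indeg = sum(1 for (s, d) in edges if d == v)
        outdeg = sum(1 for (s, d) in edges if s == v)
        if indeg == 0 and outdeg == 0:
            out[v] = "isolated"
        elif indeg == 0:
            out[v] = "source"
        elif outdeg == 0:
            out[v] = "receiver"
        else:
            out[v] = "transmitter"
    return out


def brute_diameter(nodes: list[str], edges: set[tuple[str, str]],
                   undirected: bool = False) -> int:
    """Floyd-Warshall longest finite shortest path over reachable pairs."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for s, d in edges:
        dist[idx[s]][idx[d]] = 1
        if undirected:
            dist[idx[d]][idx[s]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [dist[i][j] for i in range(n) for j in range(n) if dist[i][j] < inf]
    return max(finite)


def brute_simple_cycles(signed_edges: dict[tuple[str, str], int]
                        ) -> set[tuple[tuple[str, ...], int]]:
    """All vertex-simple directed cycles with their sign products.

    Each cycle is reported once, rotated so its lexicographically smallest
    node comes first.
    """
    succ: dict[str, list[str]] = {}
    for (s, d) in signed_edges:
        succ.setdefault(s, []).append(d)
    found: set[tuple[tuple[str, ...], int]] = set()

    def dfs(start: str, node: str, path: list[str]) -> None:
        for nxt in succ.get(node, []):
            if nxt == start:
                if path[0] == min(path):  # canonical start only
                    sign = 1
                    for i in range(len(path)):
                        sign *= signed_edges[(path[i], path[(i + 1) % len(path)])]
                    found.add((tuple(path), sign))
            elif nxt not in path and nxt > start:
                dfs(start, nxt, path + [nxt])

    for v in succ:
        dfs(v, v, [v])
    return found


def brute_path_sign_products(
    signed_edges: dict[tuple[str, str], int], u: str, v: str,
    allowed_interior: set[str],
) -> list[int]:
    """Sign products of every simple u->v path whose interior nodes all
    lie in ``allowed_interior`` (pure DFS enumeration)."""
    succ: dict[str, list[str]] = {}
    for (s, d) in signed_edges:
        succ.setdefault(s, []).append(d)
    products: list[int] = []

    def dfs(node: str, visited: set[str], sign: int) -> None:
        for nxt in succ.get(node, []):
            s2 = sign * signed_edges[(node, nxt)]
            if nxt == v:
                products.append(s2)
            elif nxt in allowed_interior and nxt not in visited:
                dfs(nxt, visited | {nxt}, s2)

    dfs(u, {u}, 1)
    return sorted(products)
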