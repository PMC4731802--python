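"""Shared fixtures: tiny PDB texts, small graphs, deterministic ensembles."""

import networkx as nx
import numpy as np
import pytest

from allopath.network import WeightedNetwork


def pdb_atom(serial, name, resname, chain, resid, x, y, z, element=None):
    element = element or name[0]
    pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"ATOM  {serial:5d} {pname} {resname:<3s} {chain}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}\n")


@pytest.fixture
def one_residue_pdb(tmp_path):
    """A single alanine-like residue with 5 atoms."""
    lines = [
        pdb_atom(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_atom(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
        pdb_atom(3, "C", "ALA", "A", 1, 2.1, 1.4, 0.0, "C"),
        pdb_atom(4, "O", "ALA", "A", 1, 1.5, 2.4, 0.0, "O"),
        pdb_atom(5, "CB", "ALA", "A", 1, 2.0, -0.8, 1.2, "C"),
    ]
    path = tmp_path / "one.pdb"
    path.write_text("".join(lines) + "END\n")
    return str(path)


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Three protein residues on chain A plus one DNA residue on chain B."""
    lines = []
    serial = 0
    for resid in range(1, 4):
        for name, elem, dx in (("N", "N", 0.0), ("CA", "C", 1.5), ("C", "C", 2.5)):
            serial += 1
            lines.append(pdb_atom(serial, name, "GLY", "A", resid,
                                  resid * 4.0 + dx, 0.0, 0.0, elem))
    for name, elem, dy in (("P", "P", 0.0), ("C1'", "C", 1.2), ("N1", "N", 2.2)):
        serial += 1
        lines.append(pdb_atom(serial, name, "DA", "B", 1, 0.0, 8.0 + dy, 0.0, elem))
    path = tmp_path / "two_chain.pdb"
    path.write_text("".join(lines) + "END\n")
    return str(path)


def build_net(edges, gc_default=1.0):
    """WeightedNetwork from (u, v[, length]) tuples; gc defaults to 1."""
    G = nx.Graph()
    for e in edges:
        u, v = e[0], e[1]
        length = e[2] if len(e) > 2 else 0.5
        G.add_edge(u, v, gc=gc_default, weight=gc_default, length=length)
    return WeightedNetwork(graph=G)


@pytest.fixture
def two_k5_bridge():
    """Two 5-cliques joined by a single bridge edge, uniform weights."""
    edges = []
    for base in (0, 5):
        edges += [(base + i, base + j) for i in range(5) for j in range(i + 1, 5)]
    edges.append((0, 5))
    return build_net(edges)


def random_weighted_graph(rng, n_nodes, p=0.5):
    """Connected random graph with lengths in (0.1, 1.1); retries until connected."""
    while True:
        G = nx.Graph()
        G.add_nodes_from(range(n_nodes))
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p:
                    w = rng.uniform(0.1, 1.1)
                    G.add_edge(i, j, gc=np.exp(-w), weight=np.exp(-w), length=w)
        if nx.is_connected(G):
            return WeightedNetwork(graph=G)
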