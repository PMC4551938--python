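"""Shared fixtures: synthetic structures, models and PDB text builders."""

import numpy as np
import pytest

import rnaenm as r


def make_pdb_line(serial, name, res_name, chain, res_id, xyz, occupancy=1.0,
                  element=None, hetero=False, altloc=" ", icode=" "):
    """One fixed-column ATOM/HETATM record."""
    element = element or name.strip()[0]
    record = "HETATM" if hetero else "ATOM  "
    # PDB convention: names of 1-3 characters start in column 14
    field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record}{serial:>5d} {field}{altloc}{res_name:>3s} {chain}"
            f"{res_id:>4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}")


def make_chain_pdb(n_residues=8, chain="A", drop_5prime_p=True, extra_atoms=2,
                   seed=7):
    """PDB text for a single RNA-like chain with P, C1', C2 and extras.

    Returns (text, n_heavy_atoms).  Coordinates are a loose irregular helix
    (deterministic for the given seed).
    """
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    n_heavy = 0
    for t in range(n_residues):
        base = np.array([4.0 * np.cos(0.6 * t), 4.0 * np.sin(0.6 * t), 2.5 * t])
        names = ["P", "C1'", "C2"] + [f"N{k + 1}" for k in range(extra_atoms)]
        if drop_5prime_p and t == 0:
            names.remove("P")
        for name in names:
            xyz = base + rng.uniform(-0.8, 0.8, 3)
            lines.append(make_pdb_line(serial, name, "U", chain, t + 1, xyz))
            serial += 1
            n_heavy += 1
    lines.append("END")
    return "\n".join(lines) + "\n", n_heavy


@pytest.fixture(scope="session")
def duplex():
    return r.generate_duplex()


@pytest.fixture(scope="session")
def duplex_model(duplex):
    """SBP ENM of the 16-bp duplex at a 9 Å cutoff."""
    return r.covariance_from_hessian(r.hessian(r.build_network(duplex, 9.0)))


@pytest.fixture(scope="session")
def cloud_network_factory():
    """Connected random-cloud networks for property checks."""

    def make(n=10, seed=0, cutoff=None, box=14.0, min_separation=2.5):
        cloud = r.random_cloud(n, box=box, min_separation=min_separation, seed=seed)
        if cutoff is None:
            # guarantee full connectivity: beyond the largest pair distance
            from scipy.spatial.distance import pdist
            cutoff = float(pdist(cloud.coords).max()) + 1.0
        return cloud, r.build_network(cloud, cutoff)

    return make


def dof_indices(bead_indices):
    idx = np.asarray(bead_indices, dtype=int)
    return (3 * idx[:, None] + np.arange(3)).ravel()
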