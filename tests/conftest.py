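"""Shared fixtures and independent oracles.

The oracles here are deliberately naive — python loops and dense numpy —
so they share no code path with the package's sparse/blocked
implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hicbox import ChromosomeTable, ContainerReader, GenomicLocus, build_container
from hicbox.synthetic import LoopSpec, SyntheticConfig, simulate_contacts

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles


def oracle_dense_pair(records, table, chrom_x, chrom_y, resolution):
    """Brute-force full-grid binning for one chromosome pair.

    ``records`` are (chr1, pos1, chr2, pos2, count) with 1-based positions.
    Returns the dense (n_bins_x, n_bins_y) matrix with intra-chromosomal
    symmetry applied (diagonal counted once).
    """
    nx = math.ceil(table[chrom_x].length / resolution)
    ny = math.ceil(table[chrom_y].length / resolution)
    M = np.zeros((nx, ny))
    for c1, p1, c2, p2, cnt in records:
        b1 = (p1 - 1) // resolution
        b2 = (p2 - 1) // resolution
        if chrom_x == chrom_y:
            if c1 == chrom_x and c2 == chrom_x:
                M[b1, b2] += cnt
                if b1 != b2:
                    M[b2, b1] += cnt
        else:
            if (c1, c2) == (chrom_x, chrom_y):
                M[b1, b2] += cnt
            elif (c1, c2) == (chrom_y, chrom_x):
                M[b2, b1] += cnt
    return M


def oracle_vc(row_sums, sqrt=False):
    """Dense vanilla-coverage factors (NaN at zero coverage)."""
    row_sums = np.asarray(row_sums, float)
    v = np.full(len(row_sums), np.nan)
    nz = row_sums > 0
    if nz.any():
        v[nz] = row_sums[nz] / row_sums[nz].mean()
        if sqrt:
            v[nz] = np.sqrt(v[nz])
    return v


def oracle_balanced(M, tol=1e-5, max_iter=200):
    """Dense iterative proportional scaling (same update rule, dense path)."""
    M = np.asarray(M, float)
    row = M.sum(axis=1)
    active = row > 0
    v = np.full(M.shape[0], np.nan)
    if not active.any():
        return v
    v[active] = 1.0
    best_v, best_dev = v.copy(), np.inf
    converged = False
    for _ in range(max_iter + 1):
        x = np.where(active, 1.0 / v, 0.0)
        s = (M * x[None, :]).sum(axis=1) * x
        m = s[active].mean()
        dev = np.max(np.abs(s[active] / m - 1.0))
        if dev < best_dev:
            best_dev, best_v = dev, v.copy()
        if dev < tol:
            converged = True
            break
        v[active] *= np.sqrt(s[active] / m)
    return v if converged else best_v


def oracle_normalized(M_slice, vx, vy):
    """Apply factors densely; NaN factors poison the row/column."""
    out = M_slice / np.outer(vx, vy)
    return out


def random_records(rng, table, n, max_count=3, with_count=True):
    """Random 1-based contact records over a chromosome table."""
    names = table.names()
    recs = []
    for _ in range(n):
        c1, c2 = rng.choice(names), rng.choice(names)
        p1 = int(rng.integers(1, table[c1].length + 1))
        p2 = int(rng.integers(1, table[c2].length + 1))
        cnt = float(rng.integers(1, max_count + 1)) if with_count else 1.0
        recs.append((c1, p1, c2, p2, cnt))
    return recs


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def toy_table():
    return ChromosomeTable([("chrA", 1000), ("chrB", 800)])


@pytest.fixture()
def toy_container(tmp_path, toy_table):
    """Small fixed container over the toy genome, three resolutions."""
    rng = np.random.default_rng(42)
    recs = random_records(rng, toy_table, 300)
    path = tmp_path / "toy.hicj"
    build_container(recs, toy_table, str(path), resolutions=[500, 250, 100])
    reader = ContainerReader(str(path))
    yield reader, recs, str(path)
    reader.close()


@pytest.fixture(scope="session")
def loop_fixture():
    """Synthetic map with one strong loop and one domain, default genome."""
    cfg = SyntheticConfig(
        n_contacts=500_000,
        seed=7,
        loops=(LoopSpec(1_000_000, 2_000_000, 8.0, radius=20_000),),
        domains=(),
    )
    return simulate_contacts(cfg)


@pytest.fixture(scope="session")
def loop_container(tmp_path_factory, loop_fixture):
    """The loop fixture built into a container at its working resolution."""
    path = tmp_path_factory.mktemp("loopmap") / "loop.hicj"
    build_container(
        loop_fixture.contacts_dataframe(),
        loop_fixture.chrom_table(),
        str(path),
        resolutions=[10_000],
    )
    reader = ContainerReader(str(path))
    yield reader, loop_fixture, str(path)
    reader.close()


@pytest.fixture(scope="session")
def big_container(tmp_path_factory):
    """~1.6 MB container with >=100 blocks, for transfer-bound tests."""
    cfg = SyntheticConfig(n_contacts=2_000_000, resolution=1000, d0=1000, seed=11)
    result = simulate_contacts(cfg)
    path = tmp_path_factory.mktemp("bigmap") / "big.hicj"
    build_container(
        result.contacts_dataframe(), result.chrom_table(), str(path), resolutions=[1000]
    )
    return str(path)


@pytest.fixture()
def full_locus():
    def make(table, name):
        return GenomicLocus(name, 0, table[name].length)

    return make
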