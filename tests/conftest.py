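import numpy as np
import pandas as pd
import pytest

from olfatlas.synthetic_data import (
    SimulationConfig,
    gen_count_matrix,
    gen_ligand_annotations,
    gen_or_catalog,
    gen_orthology,
)
import olfatlas.quantify as quantify


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def catalogs(cfg):
    return {sp: gen_or_catalog(cfg, sp) for sp in cfg.species}


@pytest.fixture(scope="session")
def species_data(cfg, catalogs):
    """Per-species normalized data, abundance tables, and top-decile sets."""
    out = {}
    for sp in cfg.species:
        cat = catalogs[sp]
        pairs, mult = gen_ligand_annotations(cat, cfg, sp)
        counts, true_sf, true_means = gen_count_matrix(cat, cfg, sp, multipliers=mult)
        sf = quantify.estimate_size_factors(counts)
        norm = quantify.normalize(counts, sf)
        ab = quantify.summarize_abundance(norm, cat.index)
        ab["expressed"] = quantify.flag_expressed(norm).reindex(ab.index)
        top = quantify.top_decile_set(ab)
        out[sp] = dict(
            catalog=cat, pairs=pairs, multipliers=mult, counts=counts,
            true_size_factors=true_sf, true_means=true_means,
            norm=norm, abundance=ab, top=top,
        )
    return out


@pytest.fixture(scope="session")
def orthology(cfg, catalogs):
    table, truth = gen_orthology(catalogs, cfg)
    return table, truth


def brute_silhouette(D, labels):
    """Definitional silhouette oracle: explicit loops, no vectorization."""
    D = np.asarray(D, float)
    labels = list(labels)
    n = len(labels)
    clusters = sorted(set(labels))
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = sum(D[i][j] for j in own) / len(own)
        bs = []
        for c in clusters:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            bs.append(sum(D[i][j] for j in members) / len(members))
        b = min(bs)
        svals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return sum(svals) / n


def brute_pearson_gamma(D, labels):
    D = np.asarray(D, float)
    labels = list(labels)
    d, ind = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d.append(D[i][j])
            ind.append(0.0 if labels[i] == labels[j] else 1.0)
    d, ind = np.array(d), np.array(ind)
    return float(np.corrcoef(d, ind)[0, 1])


def brute_wb_ratio(D, labels):
    D = np.asarray(D, float)
    labels = list(labels)
    within, between = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            (within if labels[i] == labels[j] else between).append(D[i][j])
    return float(np.mean(within) / np.mean(between))


def random_dissimilarity_instance(rng, n_max=12):
    """Random metric-free dissimilarity matrix with a random labeling."""
    n = int(rng.integers(4, n_max + 1))
    A = rng.random((n, n))
    D = np.triu(A, 1)
    D = D + D.T
    k = int(rng.integers(2, min(4, n - 1) + 1))
    labels = rng.integers(1, k + 1, size=n)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(1, k + 1, size=n)
    return D, labels
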