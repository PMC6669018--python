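"""Synthetic fixture generators emulating the statistical structure of
cross-species olfactory mucosa RNA-seq.

Every downstream stage of the pipeline is testable without any download:
these generators produce OR catalogs (intact / pseudogene / truncated,
class I / II), negative-binomial count matrices with heavy-tailed
(log-normal) mean abundances and planted per-sample size factors, 1:1
orthology tables with planted complete intact groups, OR–ligand pair tables
with a planted abundance elevation for a designated ligand class,
physicochemical descriptor matrices with planted removal targets, and a toy
annotation fixture exercising every merge rule. Each generator returns the
latent ground truth the recovery tests need.

Determinism: a single global seed drives one named stream per generator
(via ``numpy.random.SeedSequence`` spawn keys), so adding a generator never
perturbs another's draws, and identical seed + config give bit-identical
output.
"""

from __future__ import annotations

import json
import hashlib
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .or_annotation import AlignmentHit, GtfRecord, MergeReport, write_hits_tsv, write_gtf

__all__ = [
    "SimulationConfig",
    "AnnotationFixture",
    "gen_or_catalog",
    "gen_count_matrix",
    "gen_orthology",
    "gen_ligand_annotations",
    "gen_descriptor_matrix",
    "gen_annotation_fixture",
    "materialize",
]

_DEFAULT_SPECIES = ("dog", "mouse", "rat", "marmoset", "macaque", "human")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the profiled study design: six species, three
    replicates each, a few hundred OR genes per species with a heavy-tailed
    (log-normal) abundance distribution, negative-binomial count noise,
    73 planted complete 1:1 intact ortholog groups (18 class I, 55
    class II), and a 2.4-fold abundance elevation planted for the
    designated ligand class.
    """

    seed: int = 0
    species: tuple[str, ...] = _DEFAULT_SPECIES
    n_or_per_species: int = 400
    pseudo_fraction: float = 0.30
    truncated_fraction: float = 0.05
    classI_fraction: float = 0.20
    n_samples_per_species: dict[str, int] | int = 3
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    abundance_shape: tuple[float, float] = (4.0, 1.8)  # (mu, sigma) of ln mean abundance
    pseudo_expression_scale: float = 0.1
    nb_dispersion: float = 25.0
    planted_fold: float = 2.4
    planted_class: str = "KFO"
    ligand_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"KFO": 0.10, "SMC": 0.04, "other": 0.08}
    )
    n_ogg: int = 73
    n_ogg_classI: int = 18

    @property
    def n_species(self) -> int:
        return len(self.species)

    def n_samples(self, species: str) -> int:
        if isinstance(self.n_samples_per_species, dict):
            return int(self.n_samples_per_species[species])
        return int(self.n_samples_per_species)

    def __post_init__(self):
        for name in ("pseudo_fraction", "truncated_fraction", "classI_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.pseudo_fraction + self.truncated_fraction > 1.0:
            raise ValueError("pseudo_fraction + truncated_fraction must not exceed 1")
        if self.planted_fold <= 0:
            raise ValueError("planted_fold must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.size_factor_range
        if not 0 < lo <= hi:
            raise ValueError("size_factor_range must satisfy 0 < low <= high")
        if sum(self.ligand_class_fractions.values()) > 1.0:
            raise ValueError("ligand class fractions sum to more than 1")
        if any(f < 0 for f in self.ligand_class_fractions.values()):
            raise ValueError("ligand class fractions must be nonnegative")
        if self.n_ogg_classI > self.n_ogg:
            raise ValueError("n_ogg_classI cannot exceed n_ogg")


def _rng(cfg: SimulationConfig, stream: str, *extra: int) -> np.random.Generator:
    """Named substream of the global seed; stable across generator additions."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(key, *extra)))


def _species_index(cfg: SimulationConfig, species: str) -> int:
    try:
        return cfg.species.index(species)
    except ValueError:
        raise KeyError(f"species {species!r} not in config species {cfg.species}")


# ---------------------------------------------------------------------------
# OR catalogs

def gen_or_catalog(cfg: SimulationConfig, species: str) -> pd.DataFrame:
    """OR catalog for one species: id, status, receptor class.

    Status is drawn per gene from (intact, pseudogene, truncated) with the
    configured fractions; class I membership is Bernoulli with
    ``classI_fraction``. Index = OR id.
    """
    if cfg.n_or_per_species == 0:
        raise ValueError("empty catalog: n_or_per_species is 0")
    rng = _rng(cfg, "catalog", _species_index(cfg, species))
    n = cfg.n_or_per_species
    probs = [1.0 - cfg.pseudo_fraction - cfg.truncated_fraction,
             cfg.pseudo_fraction, cfg.truncated_fraction]
    status = rng.choice(["intact", "pseudogene", "truncated"], size=n, p=probs)
    or_class = np.where(rng.random(n) < cfg.classI_fraction, "I", "II")
    ids = [f"{species}_OR{i:04d}" for i in range(n)]
    return pd.DataFrame({"status": status, "or_class": or_class},
                        index=pd.Index(ids, name="or_id"))


# ---------------------------------------------------------------------------
# ligand annotations (before counts: they set the abundance multipliers)

_ODORANT_CLASSES = (
    "carboxylic acid", "thiol", "vanillin-like", "aldehyde", "alcohol",
    "ketone", "terpene", "azine", "camphor", "ester", "lactone",
)
_DESCRIPTORS = (
    "cheesy", "sweaty", "sulfurous", "sweet", "fruity", "floral",
    "minty", "nutty", "green", "buttery", "animalic", "pungent",
)


def gen_ligand_annotations(
    catalog: pd.DataFrame, cfg: SimulationConfig, species: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign odorant ligands and class labels to a subset of intact ORs.

    Each ligand class in ``cfg.ligand_class_fractions`` claims its fraction
    of the intact ORs (disjoint sets); each labeled OR receives 1–3 odorant
    pairs carrying the class flags, a chemical class, and descriptor tags.
    Returns the long pair table and a per-OR abundance multiplier series:
    ORs of the planted class get ``cfg.planted_fold``, everything else 1.
    The multiplier must be applied *before* count generation.
    """
    rng = _rng(cfg, "ligands", _species_index(cfg, species))
    intact = catalog.index[catalog["status"] == "intact"]
    multipliers = pd.Series(1.0, index=catalog.index, name="abundance_multiplier")
    pool = list(intact)
    rng.shuffle(pool)
    rows = []
    offset = 0
    for cls, frac in sorted(cfg.ligand_class_fractions.items()):
        n_cls = int(round(frac * len(intact)))
        chosen = pool[offset:offset + n_cls]
        offset += n_cls
        for or_id in chosen:
            if cls == cfg.planted_class:
                multipliers[or_id] = cfg.planted_fold
            for _ in range(int(rng.integers(1, 4))):
                odorant = f"odorant_{rng.integers(0, 10_000):05d}"
                rows.append({
                    "or_id": or_id,
                    "species": species,
                    "odorant_id": odorant,
                    "is_kfo": cls == "KFO",
                    "is_smc": cls == "SMC",
                    "chemical_class": str(rng.choice(_ODORANT_CLASSES)),
                    "descriptors": ";".join(
                        sorted(rng.choice(_DESCRIPTORS, size=2, replace=False))
                    ),
                })
    pairs = pd.DataFrame(
        rows,
        columns=["or_id", "species", "odorant_id", "is_kfo", "is_smc",
                 "chemical_class", "descriptors"],
    )
    return pairs, multipliers


# ---------------------------------------------------------------------------
# counts

def gen_count_matrix(
    catalog: pd.DataFrame,
    cfg: SimulationConfig,
    species: str,
    multipliers: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial counts with heavy-tailed means and planted size factors.

    Gene mean abundances are log-normal (``abundance_shape = (mu, sigma)``
    of the underlying normal); pseudogene and truncated genes are scaled
    down by ``pseudo_expression_scale``; optional per-gene multipliers (the
    planted ligand-class fold) multiply the means. Counts for gene g in
    sample s are NB with mean ``abundance_g * size_factor_s`` and dispersion
    ``nb_dispersion`` (variance m + m^2/dispersion; the infinite-dispersion
    limit is Poisson). Size factors are drawn uniformly from
    ``size_factor_range``.

    Returns ``(counts, true_size_factors, true_mean_abundances)``.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = _rng(cfg, "counts", _species_index(cfg, species))
    n_genes = len(catalog)
    n_samples = cfg.n_samples(species)
    mu, sigma = cfg.abundance_shape
    abundance = rng.lognormal(mean=mu, sigma=sigma, size=n_genes)
    disrupted = (catalog["status"] != "intact").to_numpy()
    abundance[disrupted] *= cfg.pseudo_expression_scale
    if multipliers is not None:
        abundance *= multipliers.reindex(catalog.index).fillna(1.0).to_numpy()
    lo, hi = cfg.size_factor_range
    size_factors = rng.uniform(lo, hi, size=n_samples)
    mean = abundance[:, None] * size_factors[None, :]
    r = cfg.nb_dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    samples = [f"{species}_rep{j + 1}" for j in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=catalog.index, columns=samples)
    return (
        counts_df,
        pd.Series(size_factors, index=samples, name="size_factor"),
        pd.Series(abundance, index=catalog.index, name="true_mean_abundance"),
    )


# ---------------------------------------------------------------------------
# orthology

def gen_orthology(
    catalogs: dict[str, pd.DataFrame],
    cfg: SimulationConfig,
    *,
    n_incomplete: int = 20,
    n_low_identity: int = 10,
    n_with_pseudogene: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orthology table with planted complete 1:1 intact groups plus distractors.

    Plants ``cfg.n_ogg`` complete groups (one intact gene per species, class
    I for the first ``n_ogg_classI``, class II for the rest, amino-acid
    identity to the human ortholog >= 40%), then distractor groups: groups
    missing one species, groups below 40% identity, and groups containing a
    pseudogene member. Returns ``(table, truth)`` where truth has one row
    per planted complete group (group id and class).
    """
    if len(catalogs) < 2:
        raise ValueError("need catalogs for >= 2 species")
    if set(catalogs) != set(cfg.species):
        raise ValueError(
            f"catalog species {sorted(catalogs)} do not match config species {sorted(cfg.species)}"
        )
    rng = _rng(cfg, "orthology")
    pools: dict[str, dict[str, list[str]]] = {}
    for sp, cat in catalogs.items():
        pools[sp] = {
            "I": list(cat.index[(cat["status"] == "intact") & (cat["or_class"] == "I")]),
            "II": list(cat.index[(cat["status"] == "intact") & (cat["or_class"] == "II")]),
            "pseudo": list(cat.index[cat["status"] == "pseudogene"]),
        }
        for pool in pools[sp].values():
            rng.shuffle(pool)
    needed_I = cfg.n_ogg_classI
    needed_II = cfg.n_ogg - cfg.n_ogg_classI
    for sp in cfg.species:
        if len(pools[sp]["I"]) < needed_I or len(pools[sp]["II"]) < needed_II:
            raise ValueError(f"catalog for {sp!r} too small for the planted group counts")
    # distractor counts shrink to what the smallest catalog can support
    spare_II = min(len(pools[sp]["II"]) - needed_II for sp in cfg.species)
    spare_pseudo = min(len(pools[sp]["pseudo"]) for sp in cfg.species)
    while n_incomplete + n_low_identity + n_with_pseudogene > spare_II or (
        n_low_identity + n_with_pseudogene > spare_pseudo
    ):
        n_incomplete = max(0, n_incomplete - 1)
        n_low_identity = max(0, n_low_identity - 1)
        n_with_pseudogene = max(0, n_with_pseudogene - 1)
        if n_incomplete == n_low_identity == n_with_pseudogene == 0:
            break

    rows, truth_rows = [], []
    gid = 0

    def take(sp: str, pool: str) -> str:
        return pools[sp][pool].pop()

    for i in range(cfg.n_ogg):
        cls = "I" if i < cfg.n_ogg_classI else "II"
        gid += 1
        row = {"group_id": f"G{gid:04d}",
               "aa_identity_to_human": float(np.round(rng.uniform(55, 95), 2))}
        for sp in cfg.species:
            row[sp] = take(sp, cls)
        rows.append(row)
        truth_rows.append({"group_id": row["group_id"], "or_class": cls})
    for _ in range(n_incomplete):
        gid += 1
        row = {"group_id": f"G{gid:04d}",
               "aa_identity_to_human": float(np.round(rng.uniform(45, 95), 2))}
        drop_sp = cfg.species[int(rng.integers(len(cfg.species)))]
        for sp in cfg.species:
            row[sp] = None if sp == drop_sp else take(sp, "II")
        rows.append(row)
    for _ in range(n_low_identity):
        # fail the aa-identity rule; also carry a pseudogene member so the
        # intact-only OGG assembly excludes them independently
        gid += 1
        row = {"group_id": f"G{gid:04d}",
               "aa_identity_to_human": float(np.round(rng.uniform(10, 39.9), 2))}
        pseudo_sp = cfg.species[int(rng.integers(len(cfg.species)))]
        for sp in cfg.species:
            row[sp] = take(sp, "pseudo") if sp == pseudo_sp else take(sp, "II")
        rows.append(row)
    for _ in range(n_with_pseudogene):
        gid += 1
        row = {"group_id": f"G{gid:04d}",
               "aa_identity_to_human": float(np.round(rng.uniform(45, 95), 2))}
        pseudo_sp = cfg.species[int(rng.integers(len(cfg.species)))]
        for sp in cfg.species:
            row[sp] = take(sp, "pseudo") if sp == pseudo_sp else take(sp, "II")
        rows.append(row)
    table = pd.DataFrame(rows, columns=["group_id", *cfg.species, "aa_identity_to_human"])
    truth = pd.DataFrame(truth_rows, columns=["group_id", "or_class"])
    return table, truth


# ---------------------------------------------------------------------------
# descriptor matrices

def gen_descriptor_matrix(
    cfg: SimulationConfig,
    *,
    n_odorants: int = 100,
    n_clean: int = 60,
    n_constant: int = 5,
    n_near_constant: int = 5,
    n_mode_ratio: int = 5,
    n_missing: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Odorant x descriptor matrix with planted removal targets.

    Planted columns: exactly constant and near-constant (modal frequency
    > 0.9), mode-ratio violators (modal count > 19x the second mode while
    modal frequency <= 0.9), and columns with one missing value. Clean
    columns are continuous draws (every value distinct with probability 1).
    Returns the matrix and a per-descriptor truth series with values in
    {"keep", "missing", "near_constant", "mode_ratio"} — the rule a
    compliant filter should report.
    """
    if n_odorants < 30:
        raise ValueError("need >= 30 odorants for the planted structures")
    rng = _rng(cfg, "descriptors")
    odorants = [f"mol_{i:04d}" for i in range(n_odorants)]
    cols: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}

    def add(name, values, label):
        cols[name] = values
        truth[name] = label

    for i in range(n_clean):
        add(f"clean_{i:03d}", rng.normal(size=n_odorants), "keep")
    for i in range(n_constant):
        add(f"const_{i:02d}", np.full(n_odorants, float(rng.integers(0, 5))), "near_constant")
    for i in range(n_near_constant):
        v = np.full(n_odorants, 1.0)
        n_other = max(1, int(np.floor(0.08 * n_odorants)))  # modal freq > 0.9
        v[rng.choice(n_odorants, size=n_other, replace=False)] = rng.normal(size=n_other) + 10
        add(f"nearconst_{i:02d}", v, "near_constant")
    for i in range(n_mode_ratio):
        # modal count ~ 0.6n (freq <= 0.9) but second mode count 1 -> ratio > 19
        v = rng.normal(size=n_odorants)
        n_modal = int(np.floor(0.6 * n_odorants))
        v[:n_modal] = 7.0
        add(f"moderatio_{i:02d}", rng.permutation(v), "mode_ratio")
    for i in range(n_missing):
        v = rng.normal(size=n_odorants)
        v[int(rng.integers(n_odorants))] = np.nan
        add(f"missing_{i:02d}", v, "missing")
    order = rng.permutation(sorted(cols))
    matrix = pd.DataFrame({c: cols[c] for c in order}, index=pd.Index(odorants, name="odorant_id"))
    return matrix, pd.Series({c: truth[c] for c in order}, name="removal_truth")


# ---------------------------------------------------------------------------
# annotation fixture

@dataclass(frozen=True)
class AnnotationFixture:
    """Toy chromosome with hits engineered to exercise every merge rule."""

    base: list[GtfRecord]
    hits: list[AlignmentHit]
    expected: MergeReport
    expected_kept_or_ids: frozenset[str]


def gen_annotation_fixture(cfg: SimulationConfig) -> AnnotationFixture:
    """Base GTF records plus OR hits with a known post-merge inventory.

    The fixture plants, on one toy chromosome: a hit below the 95% identity
    threshold, a receptor mapping to two loci (multimapper), an overlapping
    pair with a clear best hit whose winner also replaces a base gene, an
    exact-identity tie resolved by the seed, an intergenic unique hit, and a
    hit spanning two base annotations. The expected MergeReport is
    constructed alongside; the tie winner is determined by replaying the
    overlap resolution on the tie pair alone, so the expectation is fixed by
    ``cfg.seed`` without peeking at the full pipeline.
    """
    chrom = "chrT"

    def gtf(gene_id: str, start: int, end: int) -> GtfRecord:
        return GtfRecord(
            seqname=chrom, source="base", feature="gene", start=start, end=end,
            strand="+", attributes=(("gene_id", gene_id),),
        )

    base = [
        gtf("G1", 1001, 1900),    # replaced by ORA
        gtf("G2", 5001, 5400),    # replaced by ORF (spans G2+G3)
        gtf("G3", 5600, 6000),
        gtf("G4", 9001, 9900),    # untouched
    ]

    def hit(or_id, start, end, matches, mismatches, gaps=0):
        return AlignmentHit(
            or_id=or_id, chrom=chrom, start=start, end=end, strand="+",
            matches=matches, mismatches=mismatches, query_gap_bases=gaps,
            query_length=matches + mismatches + gaps,
        )

    low = hit("OR_low", 100, 1030, 94, 6)                 # 94% -> dropped
    multi1 = hit("OR_multi", 2000, 2930, 97, 3)           # multimapper
    multi2 = hit("OR_multi", 7000, 7930, 96, 4)
    ora = hit("ORA", 1100, 2030, 97, 3)                   # best of overlap pair; replaces G1
    orb = hit("ORB", 1500, 2430, 96, 4)                   # overlaps ORA, worse -> dropped
    orc = hit("ORC", 3000, 3930, 97, 3)                   # tie pair (intergenic)
    ord_ = hit("ORD", 3500, 4430, 97, 3)
    ore = hit("ORE", 8000, 8930, 98, 2)                   # intergenic unique -> appended
    orf = hit("ORF", 5300, 6230, 99, 1)                   # spans G2 and G3 -> replaces 2

    hits = [low, multi1, multi2, ora, orb, orc, ord_, ore, orf]

    # tie winner fixed by replaying resolution on the isolated tie pair with
    # the same seed (the resolver draws once per tie component)
    from .or_annotation import resolve_or_overlaps

    tie_kept, _ = resolve_or_overlaps([orc, ord_], seed=cfg.seed)
    tie_winner = tie_kept[0].or_id

    expected = MergeReport(
        n_input_hits=len(hits),
        n_dropped_low_identity=1,
        n_dropped_multimap=2,
        n_dropped_overlap=2,          # ORB + tie loser
        n_replaced_annotations=3,     # G1 by ORA; G2 and G3 by ORF
        n_appended=2,                 # tie winner + ORE
    )
    kept = frozenset({"ORA", "ORE", "ORF", tie_winner})
    return AnnotationFixture(base=base, hits=hits, expected=expected, expected_kept_or_ids=kept)


# ---------------------------------------------------------------------------
# materialization to disk

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def materialize(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full synthetic dataset as TSV/GTF and a manifest JSON.

    Emits, per species: OR catalog, raw count matrix, ligand pairs, true
    size factors; plus the orthology table, descriptor matrix, annotation
    fixture (GTF + PSL-style TSV), and a manifest recording the config and
    sha256 checksums of every file. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def save(df: pd.DataFrame | pd.Series, name: str, index=True):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        files[name] = _sha256(path)

    catalogs = {}
    for sp in cfg.species:
        cat = gen_or_catalog(cfg, sp)
        catalogs[sp] = cat
        pairs, mult = gen_ligand_annotations(cat, cfg, sp)
        counts, sf, _means = gen_count_matrix(cat, cfg, sp, multipliers=mult)
        save(cat, f"{sp}_catalog.tsv")
        save(pairs, f"{sp}_ligand_pairs.tsv", index=False)
        save(counts, f"{sp}_counts.tsv")
        save(sf, f"{sp}_true_size_factors.tsv")
    ortho, truth = gen_orthology(catalogs, cfg)
    save(ortho, "orthology.tsv", index=False)
    save(truth, "ogg_truth.tsv", index=False)
    desc, removal = gen_descriptor_matrix(cfg)
    save(desc, "descriptors.tsv")
    save(removal.rename("rule").to_frame(), "descriptor_removal_truth.tsv")
    fixture = gen_annotation_fixture(cfg)
    write_gtf(fixture.base, outdir / "base_annotation.gtf")
    files["base_annotation.gtf"] = _sha256(outdir / "base_annotation.gtf")
    write_hits_tsv(fixture.hits, outdir / "or_hits.tsv")
    files["or_hits.tsv"] = _sha256(outdir / "or_hits.tsv")

    cfg_dict = asdict(cfg)
    cfg_dict["species"] = list(cfg.species)
    manifest = {"config": cfg_dict, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
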