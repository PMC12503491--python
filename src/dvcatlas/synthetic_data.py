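"""Synthetic multi-sample single-nucleus count data with planted truth.

The generator emulates the statistical structure of a droplet-based
single-nucleus experiment at desk scale: negative-binomial UMI counts with
a skewed per-gene abundance profile, log-normal per-cell size factors, a
three-layer identity hierarchy with planted marker genes of known log2
fold-change, sample-level batch shifts, condition effects, heterotypic
doublets (sums of two singlet profiles) and depth-thinned low-quality
cells.  A fixed seed gives bit-identical output.

The planted truth (per-cell identity chain, doublet and low-quality flags,
per-gene effect table) is the oracle every downstream stage is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import make_count_matrix
from .errors import ValidationError

__all__ = [
    "Identity", "Sample", "ConditionEffect", "SimConfig", "SyntheticTruth",
    "generate_atlas", "generate_cross_species", "default_config",
    "default_cross_species_config",
]


@dataclass(frozen=True)
class Identity:
    name: str
    layer1: str
    layer2: str
    frequency: float


@dataclass(frozen=True)
class Sample:
    sample_id: str
    n_cells: int
    condition: str = "none"
    batch_log_shift: float = 0.0  # log2 units, applied to every gene


@dataclass(frozen=True)
class ConditionEffect:
    gene: str
    identities: frozenset | None  # None = all identities
    condition: str
    log2fc: float


@dataclass
class SimConfig:
    n_genes: int = 1500
    identities: list[Identity] = field(default_factory=list)
    # identity -> [(gene_name, true_log2fc >= 0), ...]
    marker_spec: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    samples: list[Sample] = field(default_factory=list)
    doublet_fraction: float = 0.06
    lowq_fraction: float = 0.05
    lowq_depth_factor: float = 0.15
    baseline_mean: float = 2.0   # mean counts per gene before abundance skew
    dispersion: float = 2.0      # NB size parameter (shared genome-wide)
    library_size_spread: float = 0.35  # sigma of log-normal size factors
    abundance_sigma: float = 0.8  # spread of per-gene baseline abundances
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    species: str = "synthetic"
    seed: int = 0
    # baseline abundances are biology of the gene universe, not noise: they
    # are drawn from their own seed so datasets simulated over the same
    # universe share them regardless of the sampling seed
    abundance_seed: int = 1234
    abundance_override: np.ndarray | None = None
    gene_names_override: list[str] | None = None

    def gene_names(self, prefix: str = "g") -> list[str]:
        if self.gene_names_override is not None:
            return list(self.gene_names_override)
        return [f"{prefix}{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes <= 0 or not self.samples or not self.identities:
            raise ValidationError("degenerate config: need genes, samples "
                                  "and identities")
        if any(s.n_cells <= 0 for s in self.samples):
            raise ValidationError("samples need n_cells > 0")
        freq = sum(i.frequency for i in self.identities)
        if abs(freq - 1.0) > 1e-6:
            raise ValidationError(f"identity frequencies sum to {freq}, not 1")
        if not (0 <= self.doublet_fraction < 1 and 0 <= self.lowq_fraction < 1):
            raise ValidationError("fractions must lie in [0, 1)")
        if not 0 < self.lowq_depth_factor < 1:
            raise ValidationError("lowq_depth_factor must lie in (0, 1)")
        genes = set(self.gene_names())
        for ident, spec in self.marker_spec.items():
            if ident not in {i.name for i in self.identities}:
                raise ValidationError(f"marker_spec for unknown identity {ident}")
            for g, fc in spec:
                if g not in genes:
                    raise ValidationError(f"marker gene {g} outside universe")
                if fc < 0:
                    raise ValidationError("marker log2fc must be >= 0")


@dataclass
class SyntheticTruth:
    cells: pd.DataFrame   # identity, layer1, layer2, is_doublet,
                          # doublet_parents, is_lowq, sample_id, condition
    effects: pd.DataFrame  # gene, identity, log2fc, kind
    config: SimConfig


def _log2_effect_matrix(cfg: SimConfig, genes: list[str]) -> pd.DataFrame:
    """identities x genes matrix of planted marker log2 fold-changes."""
    gidx = {g: j for j, g in enumerate(genes)}
    names = [i.name for i in cfg.identities]
    eff = np.zeros((len(names), len(genes)))
    for i, ident in enumerate(names):
        for g, fc in cfg.marker_spec.get(ident, []):
            eff[i, gidx[g]] = fc
    return pd.DataFrame(eff, index=names, columns=genes)


def _singlet_counts(rng, mu_identity, ident_idx, size_factors, dispersion):
    """NB draws for cells given per-identity mean profiles and size factors."""
    mu = mu_identity[ident_idx] * size_factors[:, None]
    theta = dispersion
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def generate_atlas(config: SimConfig) -> tuple["anndata.AnnData", SyntheticTruth]:
    """Generate the multi-sample count matrix and its planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_id = len(config.identities)
    names = [i.name for i in config.identities]
    freqs = np.array([i.frequency for i in config.identities])
    # skewed per-gene abundances, shared by all samples of this universe
    if config.abundance_override is not None:
        abundance = np.asarray(config.abundance_override, dtype=float)
        if abundance.shape != (config.n_genes,):
            raise ValidationError("abundance_override length mismatch")
    else:
        ab_rng = np.random.default_rng(config.abundance_seed)
        abundance = ab_rng.lognormal(mean=0.0, sigma=config.abundance_sigma,
                                     size=config.n_genes)
    abundance = abundance / abundance.mean()
    base = config.baseline_mean * abundance
    eff = _log2_effect_matrix(config, genes)
    mu_identity = base[None, :] * 2.0 ** eff.to_numpy()  # identities x genes

    blocks, obs_rows, truth_rows = [], [], []
    for sample in config.samples:
        n = sample.n_cells
        mu_s = mu_identity * 2.0 ** sample.batch_log_shift
        # condition effects for this sample's condition
        mu_cond = np.ones_like(mu_s)
        for ce in config.condition_effects:
            if ce.condition != sample.condition:
                continue
            j = genes.index(ce.gene)
            rows = (range(n_id) if ce.identities is None else
                    [names.index(i) for i in ce.identities])
            for i in rows:
                mu_cond[i, j] *= 2.0 ** ce.log2fc
        mu_s = mu_s * mu_cond

        ident_idx = rng.choice(n_id, size=n, p=freqs)
        size = rng.lognormal(mean=0.0, sigma=config.library_size_spread, size=n)
        counts = _singlet_counts(rng, mu_s, ident_idx, size, config.dispersion)

        n_doub = int(round(config.doublet_fraction * n))
        n_lowq = int(round(config.lowq_fraction * n))
        if n_doub + n_lowq > n:
            raise ValidationError("doublet + low-quality fractions exceed 1")
        slots = rng.permutation(n)
        doub_slots = slots[:n_doub]
        lowq_slots = slots[n_doub:n_doub + n_lowq]  # disjoint by construction

        # doublets: sum of two freshly drawn singlet profiles (pre-thinning)
        parents = np.stack([rng.choice(n_id, size=n_doub, p=freqs),
                            rng.choice(n_id, size=n_doub, p=freqs)], axis=1)
        if n_doub:
            s1 = rng.lognormal(0.0, config.library_size_spread, n_doub)
            s2 = rng.lognormal(0.0, config.library_size_spread, n_doub)
            d1 = _singlet_counts(rng, mu_s, parents[:, 0], s1, config.dispersion)
            d2 = _singlet_counts(rng, mu_s, parents[:, 1], s2, config.dispersion)
            counts[doub_slots] = d1 + d2
        # low-quality cells: binomial depth thinning
        if n_lowq:
            counts[lowq_slots] = rng.binomial(counts[lowq_slots],
                                              config.lowq_depth_factor)

        blocks.append(sp.csr_matrix(counts))
        is_doub = np.zeros(n, bool); is_doub[doub_slots] = True
        is_lowq = np.zeros(n, bool); is_lowq[lowq_slots] = True
        for c in range(n):
            ident = config.identities[ident_idx[c]]
            truth_rows.append({
                "cell_id": f"{sample.sample_id}:c{c:05d}",
                "sample_id": sample.sample_id,
                "condition": sample.condition,
                "layer1": ident.layer1, "layer2": ident.layer2,
                "identity": ident.name,
                "is_doublet": bool(is_doub[c]),
                "doublet_parents": (
                    f"{names[parents[list(doub_slots).index(c)][0]]}+"
                    f"{names[parents[list(doub_slots).index(c)][1]]}"
                    if is_doub[c] else ""),
                "is_lowq": bool(is_lowq[c]),
            })
            obs_rows.append({"cell_id": f"{sample.sample_id}:c{c:05d}",
                             "sample_id": sample.sample_id,
                             "condition": sample.condition,
                             "species": config.species})

    X = sp.vstack(blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = make_count_matrix(X, genes, obs.index.tolist(), cell_meta=obs)
    truth_cells = pd.DataFrame(truth_rows).set_index("cell_id")
    effect_rows = [{"gene": g, "identity": ident, "log2fc": fc,
                    "kind": "marker"}
                   for ident, spec in config.marker_spec.items()
                   for g, fc in spec]
    effect_rows += [{"gene": ce.gene,
                     "identity": ("*" if ce.identities is None
                                  else "|".join(sorted(ce.identities))),
                     "log2fc": ce.log2fc, "kind": f"condition:{ce.condition}"}
                    for ce in config.condition_effects]
    truth = SyntheticTruth(truth_cells, pd.DataFrame(effect_rows), config)
    return adata, truth


# ---------------------------------------------------------------------------
# Cross-species variant
# ---------------------------------------------------------------------------

def generate_cross_species(config_a: SimConfig, shared: list[str],
                           novel_b: list[Identity],
                           ortholog_dropout: float = 0.1,
                           samples_b: list[Sample] | None = None,
                           novel_marker_count: int = 8,
                           novel_marker_log2fc: float = 3.0):
    """Generate two species sharing identities through an ortholog map.

    Species B reuses species A's marker programs for ``shared`` identities,
    translated through a 1:1 ortholog map covering a fraction
    ``1 - ortholog_dropout`` of species-A genes (the rest are
    species-A-specific).  ``novel_b`` identities exist only in B and get
    fresh marker programs on orthologous genes.

    Returns ``(cm_a, cm_b, ortholog_table, truth_a, truth_b)``.
    """
    config_a.validate()
    names_a = {i.name for i in config_a.identities}
    if not set(shared) <= names_a:
        raise ValidationError("shared identities must exist in config_a")
    if set(shared) & {i.name for i in novel_b}:
        raise ValidationError("novel_b must be disjoint from shared")
    if not 0 <= ortholog_dropout < 1:
        raise ValidationError("ortholog_dropout must lie in [0, 1)")

    cm_a, truth_a = generate_atlas(config_a)
    rng = np.random.default_rng(config_a.seed + 1)

    genes_a = config_a.gene_names()
    n_keep = int(round((1 - ortholog_dropout) * len(genes_a)))
    kept = np.sort(rng.choice(len(genes_a), size=n_keep, replace=False))
    a2b = {genes_a[i]: f"r{i:04d}" for i in kept}
    ortho = pd.DataFrame({"gene_a": [genes_a[i] for i in kept],
                          "gene_b": [a2b[genes_a[i]] for i in kept]})

    # species-B marker programs: shared identities inherit the translated
    # program; novel identities get fresh genes never used as A markers
    used = {g for spec in config_a.marker_spec.values() for g, _ in spec}
    free = [genes_a[i] for i in kept if genes_a[i] not in used]
    rng.shuffle(free)
    marker_b: dict[str, list[tuple[str, float]]] = {}
    for ident in shared:
        marker_b[ident] = [(a2b[g], fc)
                           for g, fc in config_a.marker_spec.get(ident, [])
                           if g in a2b]
    for ident in novel_b:
        picks = [free.pop() for _ in range(novel_marker_count)]
        marker_b[ident.name] = [(a2b[g], novel_marker_log2fc) for g in picks]

    shared_ids = [i for i in config_a.identities if i.name in shared]
    total = sum(i.frequency for i in shared_ids) + sum(
        i.frequency for i in novel_b)
    ids_b = ([Identity(i.name, i.layer1, i.layer2, i.frequency / total)
              for i in shared_ids] +
             [Identity(i.name, i.layer1, i.layer2, i.frequency / total)
              for i in novel_b])
    if samples_b is None:
        samples_b = [Sample("sB1", 600), Sample("sB2", 600)]

    # rename the B universe: ortholog of gene i keeps index i, and keeps
    # species A's baseline abundance (conserved biology)
    gene_order_b = [a2b[genes_a[i]] for i in kept]
    ab_rng = np.random.default_rng(config_a.abundance_seed)
    abundance_a = (config_a.abundance_override
                   if config_a.abundance_override is not None else
                   ab_rng.lognormal(0.0, config_a.abundance_sigma,
                                    config_a.n_genes))
    abundance_b = np.asarray(abundance_a, dtype=float)[kept]
    config_b = SimConfig(
        n_genes=len(gene_order_b), identities=ids_b,
        marker_spec=marker_b, samples=samples_b,
        doublet_fraction=config_a.doublet_fraction,
        lowq_fraction=config_a.lowq_fraction,
        lowq_depth_factor=config_a.lowq_depth_factor,
        baseline_mean=config_a.baseline_mean,
        dispersion=config_a.dispersion,
        library_size_spread=config_a.library_size_spread,
        abundance_sigma=config_a.abundance_sigma,
        species=config_a.species, seed=config_a.seed + 2,
        abundance_override=abundance_b,
        gene_names_override=gene_order_b)
    cm_b, truth_b = generate_atlas(config_b)
    return cm_a, cm_b, ortho, truth_a, truth_b


def truth_hierarchy(config: SimConfig):
    """The 3-layer label tree planted by a config, as a LabelHierarchy."""
    from .hierarchy import build_tree

    recs, seen = [], set()
    for ident in config.identities:
        if ident.layer1 not in seen:
            recs.append((ident.layer1, 1, "", config.species))
            seen.add(ident.layer1)
        if ident.layer2 not in seen:
            recs.append((ident.layer2, 2, ident.layer1, config.species))
            seen.add(ident.layer2)
        recs.append((ident.name, 3, ident.layer2, config.species))
    return build_tree(recs)


# ---------------------------------------------------------------------------
# Packaged study conditions
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, cells_per_sample: int = 450,
                   n_genes: int = 1500) -> SimConfig:
    """The packaged synthetic study: 6 samples across three feeding
    conditions, 8 identities in a 3-layer hierarchy, 8 planted markers per
    identity (log2FC 2-3.5) plus 4 class-level markers, 6% doublets, 5%
    low-quality cells, and a 20-gene refeeding response in the excitatory
    class."""
    ids = [
        Identity("inhib_a", "neurons", "inhib_class", 0.16),
        Identity("inhib_b", "neurons", "inhib_class", 0.12),
        Identity("excit_a", "neurons", "excit_class", 0.18),
        Identity("excit_b", "neurons", "excit_class", 0.12),
        Identity("mono_a", "neurons", "monoamine_class", 0.08),
        Identity("astro_a", "glia", "astro_class", 0.14),
        Identity("astro_b", "glia", "astro_class", 0.06),
        Identity("oligo_a", "glia", "oligo_class", 0.14),
    ]
    rng = np.random.default_rng(seed + 941)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    pool = rng.permutation(n_genes)
    marker_spec: dict[str, list[tuple[str, float]]] = {}
    cursor = 0
    for ident in ids:
        picks = pool[cursor:cursor + 8]; cursor += 8
        fcs = rng.uniform(2.0, 3.5, size=8)
        marker_spec[ident.name] = [(genes[j], float(f))
                                   for j, f in zip(picks, fcs)]
    for cls in ["inhib_class", "excit_class", "monoamine_class",
                "astro_class", "oligo_class"]:
        picks = pool[cursor:cursor + 4]; cursor += 4
        for ident in ids:
            if ident.layer2 == cls:
                marker_spec[ident.name] += [(genes[j], 2.5) for j in picks]
    cond_genes = pool[cursor:cursor + 20]; cursor += 20
    effects = [ConditionEffect(genes[j], frozenset({"excit_a", "excit_b"}),
                               "refed", 1.5) for j in cond_genes]
    samples = [
        Sample("m1", cells_per_sample, "adlib", -0.10),
        Sample("m2", cells_per_sample, "adlib", 0.05),
        Sample("m3", cells_per_sample, "fasted", 0.10),
        Sample("m4", cells_per_sample, "fasted", -0.05),
        Sample("m5", cells_per_sample, "refed", 0.00),
        Sample("m6", cells_per_sample, "refed", 0.08),
    ]
    return SimConfig(n_genes=n_genes, identities=ids, marker_spec=marker_spec,
                     samples=samples, condition_effects=effects, seed=seed)


def default_cross_species_config(seed: int = 0):
    """Packaged cross-species benchmark: all 8 identities shared plus one
    novel species-B neuron population, 10% ortholog dropout."""
    cfg = default_config(seed=seed)
    novel = [Identity("pdgfra_neuron", "neurons", "ortus_akin", 0.10)]
    return cfg, [i.name for i in cfg.identities], novel, 0.1
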