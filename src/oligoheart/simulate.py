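"""Synthetic cohorts with known ground truth.

Generates every input the discovery pipeline consumes: an allele-frequency
reference panel, trio genotypes with Mendelian transmission plus planted
de novo / compound-heterozygous-in-trans / rare-homozygous events, a
singleton case/control cohort with planted burden in designated gene sets,
a tissue expression atlas with planted coexpression modules, and a
scale-free protein-interaction network with a planted hot module.

All generators are deterministic given a seed; per-component child seeds
are derived from the global seed by fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


BASES = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}
#: expected transition fraction chosen so the expected Ti/Tv of emitted
#: SNVs matches the 3.10 typical of well-behaved exome call sets
TI_PROB = 3.10 / 4.10

PROTEIN_ALTERING = ("missense", "LoF", "inframe-indel")
CONSEQUENCES = ("missense", "LoF", "inframe-indel", "synonymous", "other")

# fixed offsets deriving per-component child seeds from the global seed
_SEED_PANEL = 11
_SEED_TRIOS = 101
_SEED_SINGLETONS = 211
_SEED_ATLAS = 307
_SEED_PPI = 401


def gene_names(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


# ------------------------------------------------------------------ panel


@dataclass(frozen=True)
class MafSpectrum:
    """Distribution of panel minor allele frequencies on (0, 0.5].

    ``beta``: 0.5 * Beta(a, b), rare-skewed by default; ``fixed``: a point
    mass (useful for degenerate checks).
    """

    kind: str = "beta"
    a: float = 0.2
    b: float = 5.0
    value: float = 0.1
    floor: float = 1e-5

    def __post_init__(self):
        if self.kind not in ("beta", "fixed"):
            raise ConfigError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ConfigError("beta spectrum requires a > 0 and b > 0")
        if self.kind == "fixed" and not 0 < self.value <= 0.5:
            raise ConfigError("fixed spectrum value must lie in (0, 0.5]")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.value)
        maf = 0.5 * rng.beta(self.a, self.b, size=n)
        return np.clip(maf, self.floor, 0.5)

    def median(self) -> float:
        if self.kind == "fixed":
            return self.value
        return float(0.5 * beta_dist.ppf(0.5, self.a, self.b))


def simulate_panel(
    n_sites: int,
    maf_spectrum: MafSpectrum | None = None,
    seed: int = 0,
    sites_per_gene: int = 10,
    consequence_probs: dict | None = None,
) -> pd.DataFrame:
    """Reference allele-frequency panel: one row per biallelic site.

    Sites are grouped into consecutive genes (``sites_per_gene`` each),
    spread over 22 autosome labels, with ref/alt drawn under the
    transition-biased substitution model and a consequence class per site.
    MAFs are rounded to 6 decimals so emitted files round-trip losslessly.
    """
    if n_sites < 0:
        raise ConfigError("n_sites must be >= 0")
    spectrum = maf_spectrum or MafSpectrum()
    rng = np.random.default_rng(seed + _SEED_PANEL)
    n_genes = max(1, math.ceil(n_sites / sites_per_gene))
    genes = np.repeat(gene_names(n_genes), sites_per_gene)[:n_sites]
    chrom_of_gene = {g: str(1 + (i % 22)) for i, g in enumerate(gene_names(n_genes))}
    chroms = np.array([chrom_of_gene[g] for g in genes])
    pos = np.zeros(n_sites, dtype=int)
    for c in np.unique(chroms):
        mask = chroms == c
        pos[mask] = 1_000_000 + 150 * np.arange(mask.sum())
    ref = BASES[rng.integers(0, 4, size=n_sites)]
    is_ti = rng.random(n_sites) < TI_PROB
    alt = np.array(
        [
            TRANSITION[r] if ti else TRANSVERSIONS[r][rng.integers(0, 2)]
            for r, ti in zip(ref, is_ti)
        ]
    )
    probs = consequence_probs or {
        "missense": 0.50,
        "synonymous": 0.30,
        "LoF": 0.08,
        "inframe-indel": 0.05,
        "other": 0.07,
    }
    if abs(sum(probs.values()) - 1.0) > 1e-9 or set(probs) - set(CONSEQUENCES):
        raise ConfigError(f"consequence_probs must sum to 1 over {CONSEQUENCES}")
    keys = sorted(probs)
    csq = rng.choice(keys, size=n_sites, p=[probs[k] for k in keys])
    maf = np.round(spectrum.draw(rng, n_sites), 6)
    maf = np.maximum(maf, 1e-6)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": maf,
            "gene": genes,
            "consequence": csq,
        }
    )


# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class BurdenSet:
    """A gene set receiving excess case burden in the singleton cohort.

    ``effect`` multiplies the case allele frequency at every variant of the
    set (``inf`` makes every case and no control a carrier).
    """

    genes: tuple
    effect: float
    maf_max: float = 0.03  # the excess sits in rare alleles, as burden tests assume

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.effect < 0:
            raise ConfigError("burden effect must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study design of the synthetic cohorts.

    Cohort sizes default to the discovery design (59 affected + 59 control
    trios; 100 affected + 533 control singletons).  Planted-event rates are
    expected events per affected proband and default to the observed
    disease-signal density (about 18 qualifying events among 59 probands).
    """

    n_case_trios: int = 59
    n_control_trios: int = 59
    n_singleton_cases: int = 100
    n_singleton_controls: int = 533
    n_sites: int = 20_000
    n_singleton_sites: int = 2_000
    sites_per_gene: int = 10
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    rate_denovo: float = 0.10
    rate_comphet: float = 0.15
    rate_rarehom: float = 0.05
    rate_comphet_cis: float = 0.0
    planted_genes: tuple = ()
    burden_sets: tuple = ()
    depth_mean: float = 44.0
    qual_pass_fraction: float = 0.9
    missing_rate: float = 0.0
    consequence_probs: dict | None = None
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_case_trios",
            "n_control_trios",
            "n_singleton_cases",
            "n_singleton_controls",
            "n_sites",
            "n_singleton_sites",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("rate_denovo", "rate_comphet", "rate_rarehom", "rate_comphet_cis"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.qual_pass_fraction <= 1:
            raise ConfigError("qual_pass_fraction must lie in [0, 1]")
        object.__setattr__(self, "planted_genes", tuple(self.planted_genes))
        object.__setattr__(
            self, "burden_sets", tuple(BurdenSet(**b) if isinstance(b, dict) else b for b in self.burden_sets)
        )

    def noiseless(self) -> "CohortConfig":
        """Variant of this design where only planted events can qualify:
        background sites are non-protein-altering and every genotype passes
        the depth/quality thresholds."""
        return replace(
            self,
            consequence_probs={"synonymous": 0.9, "other": 0.1},
            qual_pass_fraction=1.0,
            missing_rate=0.0,
        )


# ------------------------------------------------------------------ trios


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside each synthetic cohort."""

    events: pd.DataFrame  # individual, gene, mode, variant_ids
    burden_sets: tuple = ()
    module_assignment: pd.Series | None = None
    hot_genes: tuple = ()

    def to_tsv(self, path):
        self.events.to_csv(path, sep="\t", index=False)


@dataclass
class TrioCohort:
    """In-memory trio cohort: per-site metadata plus genotype/depth/quality
    arrays of shape (n_sites, n_trios, 3) ordered child, mother, father."""

    sites: pd.DataFrame
    trios: pd.DataFrame  # family, child, mother, father, phenotype
    gt: np.ndarray
    dp: np.ndarray
    qual: np.ndarray
    truth: TruthTable | None = None

    @property
    def n_sites(self):
        return len(self.sites)

    @property
    def n_trios(self):
        return len(self.trios)

    def variant_id(self, site_idx: int) -> str:
        r = self.sites.iloc[site_idx]
        return f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"

    def mendelian_violations(self) -> np.ndarray:
        """Boolean (site, trio) mask of genotype combinations impossible
        under Mendelian transmission."""
        c, m, f = self.gt[:, :, 0], self.gt[:, :, 1], self.gt[:, :, 2]
        valid = (c >= 0) & (m >= 0) & (f >= 0)
        # alleles the child must have received: one from each parent
        child_alt = c.clip(min=0)
        max_alt = (m > 0).astype(int) + (f > 0).astype(int)
        min_alt = (m == 2).astype(int) + (f == 2).astype(int)
        return valid & ((child_alt > max_alt) | (child_alt < min_alt))


def _transmit(parent_gt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(parent_gt.shape)
    return ((parent_gt == 2) | ((parent_gt == 1) & (u < 0.5))).astype(np.int8)


def simulate_trio_cohort(config: CohortConfig) -> TrioCohort:
    """Trio genotypes under Hardy-Weinberg founders and Mendelian
    transmission, with planted inheritance events in affected probands.

    Planted events go to ``config.planted_genes`` (case probands only) and
    are forced to pass depth/quality thresholds, so the truth table lists
    exactly the detectable planted signal.  Parents of a planted de novo
    site are set homozygous reference; in-trans pairs place one heterozygous
    variant of maternal and one of paternal origin in the same gene;
    rare-homozygous events use a panel site with MAF < 0.01 and both
    parents heterozygous.
    """
    rng = np.random.default_rng(config.seed + _SEED_TRIOS)
    panel = simulate_panel(
        config.n_sites,
        config.maf_spectrum,
        seed=config.seed,
        sites_per_gene=config.sites_per_gene,
        consequence_probs=config.consequence_probs,
    )
    gene_set = set(panel["gene"])
    unknown = [g for g in config.planted_genes if g not in gene_set]
    if unknown:
        raise ConfigError(f"planted_genes absent from gene annotation: {unknown[:5]}")
    any_planting = (
        config.rate_denovo + config.rate_comphet + config.rate_rarehom + config.rate_comphet_cis
    ) > 0
    if any_planting and not config.planted_genes:
        raise ConfigError("planted rates > 0 require a non-empty planted_genes list")

    n_trios = config.n_case_trios + config.n_control_trios
    n_sites = config.n_sites
    fams = [f"FAM{i:04d}" for i in range(1, n_trios + 1)]
    trios = pd.DataFrame(
        {
            "family": fams,
            "child": [f + "_child" for f in fams],
            "mother": [f + "_mother" for f in fams],
            "father": [f + "_father" for f in fams],
            "phenotype": [2] * config.n_case_trios + [1] * config.n_control_trios,
        }
    )

    maf = panel["maf"].to_numpy()
    gt = np.zeros((n_sites, n_trios, 3), dtype=np.int8)
    gt[:, :, 1] = rng.binomial(2, maf[:, None], size=(n_sites, n_trios))
    gt[:, :, 2] = rng.binomial(2, maf[:, None], size=(n_sites, n_trios))
    gt[:, :, 0] = _transmit(gt[:, :, 1], rng) + _transmit(gt[:, :, 2], rng)

    dp = rng.poisson(config.depth_mean, size=(n_sites, n_trios, 3)).astype(np.int16)
    dp = np.maximum(dp, 1)
    # quality in [0, 1]; a configurable fraction clears the 0.5 threshold
    passing = rng.random((n_sites, n_trios, 3)) < config.qual_pass_fraction
    qual = np.where(
        passing,
        0.5 + 0.5 * rng.random((n_sites, n_trios, 3)),
        0.5 * rng.random((n_sites, n_trios, 3)),
    ).astype(np.float32)
    qual = np.round(qual, 4).astype(np.float32)
    if config.missing_rate > 0:
        miss = rng.random((n_sites, n_trios, 3)) < config.missing_rate
        gt[miss] = -1

    # ---- plant events in affected probands
    sites_by_gene = {g: idx.to_numpy() for g, idx in panel.groupby("gene").groups.items()}
    consequence = panel["consequence"].to_numpy().copy()
    maf = maf.copy()
    records = []
    used: set = set()

    def _claim(site_idx):
        # planted sites are private to one event; never reuse a site
        if site_idx in used:
            return False
        used.add(site_idx)
        return True

    def _isolate(site_idx):
        # planted variants are family-private: absent from every other
        # trio and rare in the panel, as sporadic-disease alleles are
        gt[site_idx, :, :] = 0
        maf[site_idx] = round(float(rng.uniform(1e-4, 0.009)), 6)
        consequence[site_idx] = "missense"

    def _force_pass(site_idx, trio_idx):
        dp[site_idx, trio_idx, :] = np.maximum(dp[site_idx, trio_idx, :], 10)
        qual[site_idx, trio_idx, :] = np.maximum(qual[site_idx, trio_idx, :], 0.75)

    def _vid(site_idx):
        r = panel.iloc[site_idx]
        return f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"

    planted_genes = list(config.planted_genes)
    used_gene: set = set()  # one event per (trio, gene): pairs never cross
    for t in range(config.n_case_trios):
        child = trios.at[t, "child"]
        for mode, rate in (
            ("de_novo", config.rate_denovo),
            ("compound_het", config.rate_comphet),
            ("rare_homozygous", config.rate_rarehom),
            ("cis_pair", config.rate_comphet_cis),
        ):
            for _ in range(rng.poisson(rate)):
                free = [g for g in planted_genes if (t, g) not in used_gene]
                if not free:
                    continue
                gene = free[rng.integers(0, len(free))]
                used_gene.add((t, gene))
                gsites = sites_by_gene[gene]
                if mode == "de_novo":
                    s = int(rng.choice(gsites))
                    if not _claim(s):
                        continue
                    _isolate(s)
                    gt[s, t] = (1, 0, 0)
                    _force_pass(s, t)
                    records.append((child, gene, mode, _vid(s)))
                elif mode in ("compound_het", "cis_pair"):
                    if len(gsites) < 2:
                        continue
                    s1, s2 = (int(x) for x in rng.choice(gsites, size=2, replace=False))
                    if not (_claim(s1) and _claim(s2)):
                        continue
                    _isolate(s1)
                    _isolate(s2)
                    if mode == "compound_het":
                        gt[s1, t] = (1, 1, 0)  # maternal origin
                        gt[s2, t] = (1, 0, 1)  # paternal origin
                    else:  # both maternal: in cis, must NOT be called
                        gt[s1, t] = (1, 1, 0)
                        gt[s2, t] = (1, 1, 0)
                    _force_pass(s1, t)
                    _force_pass(s2, t)
                    records.append((child, gene, mode, f"{_vid(s1)},{_vid(s2)}"))
                else:  # rare_homozygous
                    s = int(rng.choice(gsites))
                    if not _claim(s):
                        continue
                    _isolate(s)
                    gt[s, t] = (2, 1, 1)
                    _force_pass(s, t)
                    records.append((child, gene, mode, _vid(s)))

    panel = panel.assign(consequence=consequence, maf=maf)
    events = pd.DataFrame(records, columns=["individual", "gene", "mode", "variant_ids"])
    truth = TruthTable(events=events, burden_sets=config.burden_sets)
    return TrioCohort(sites=panel, trios=trios, gt=gt, dp=dp, qual=qual, truth=truth)


# ------------------------------------------------------------- singletons


@dataclass
class SingletonCohort:
    """Case/control genotype matrix for replication burden testing."""

    G: np.ndarray  # individuals x variants, dosages 0/1/2
    y: np.ndarray  # 1 case, 0 control
    variants: pd.DataFrame  # chrom, pos, ref, alt, maf, gene, consequence
    individuals: list
    truth: TruthTable | None = None


def simulate_singleton_cohort(config: CohortConfig) -> SingletonCohort:
    """Singleton cases and controls with planted excess burden.

    Control genotypes follow Hardy-Weinberg at the panel frequencies; in
    genes of each ``config.burden_sets`` entry, case allele frequencies are
    multiplied by the set's effect (``inf`` plants perfect separation).
    """
    rng = np.random.default_rng(config.seed + _SEED_SINGLETONS)
    panel = simulate_panel(
        config.n_singleton_sites,
        config.maf_spectrum,
        seed=config.seed + 1,
        sites_per_gene=config.sites_per_gene,
        consequence_probs=config.consequence_probs,
    )
    gene_set = set(panel["gene"])
    n_case, n_ctrl = config.n_singleton_cases, config.n_singleton_controls
    maf = panel["maf"].to_numpy()
    case_maf = maf.copy()
    perfect = np.zeros(len(panel), dtype=bool)
    for bs in config.burden_sets:
        missing = [g for g in bs.genes if g not in gene_set]
        if missing:
            raise ConfigError(f"burden-set genes absent from annotation: {missing}")
        mask = panel["gene"].isin(bs.genes).to_numpy() & (maf <= bs.maf_max)
        if math.isinf(bs.effect):
            perfect |= mask
            continue
        boosted = maf[mask] * bs.effect
        if np.any(boosted > 1.0):
            raise ConfigError(
                f"effect {bs.effect} drives an allele frequency above 1 in {bs.genes}"
            )
        case_maf[mask] = boosted

    G_case = rng.binomial(2, np.clip(case_maf, 0, 1)[None, :], size=(n_case, len(panel)))
    G_ctrl = rng.binomial(2, maf[None, :], size=(n_ctrl, len(panel)))
    if perfect.any():
        G_case[:, perfect] = 1
        G_ctrl[:, perfect] = 0
    G = np.vstack([G_case, G_ctrl]).astype(np.int8)
    y = np.array([1] * n_case + [0] * n_ctrl)
    individuals = [f"CASE{i:04d}" for i in range(1, n_case + 1)] + [
        f"CTRL{i:04d}" for i in range(1, n_ctrl + 1)
    ]
    truth = TruthTable(events=pd.DataFrame(columns=["individual", "gene", "mode", "variant_ids"]),
                       burden_sets=config.burden_sets)
    return SingletonCohort(G=G, y=y, variants=panel, individuals=individuals, truth=truth)


# ------------------------------------------------------------------ atlas


@dataclass(frozen=True)
class ExpressionModuleSpec:
    name: str
    genes: tuple
    tissue: str
    strength: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))


def simulate_expression_atlas(
    n_genes: int,
    n_tissues: int,
    module_spec=(),
    seed: int = 0,
    libs_per_tissue: int = 3,
    tissue_names=None,
    base_log_mean: float = 3.0,
    base_log_sd: float = 0.7,
    noise_sd: float = 0.3,
    poisson: bool = True,
):
    """Tissue-by-gene count atlas with planted coexpression modules.

    Each module's genes share a log-scale activation of ``strength`` in the
    libraries of the module's tissue, on top of gene-specific baselines and
    Gaussian log-noise; counts are Poisson unless ``poisson=False`` (then
    rounded expectations, useful for exact degenerate checks).

    Returns ``(counts, design, assignment)``: genes x libraries integer
    counts, library -> tissue labels, and gene -> module-name labels
    ('none' outside planted modules).
    """
    rng = np.random.default_rng(seed + _SEED_ATLAS)
    genes = gene_names(n_genes)
    tissues = list(tissue_names) if tissue_names is not None else [
        f"tissue{i:02d}" for i in range(1, n_tissues + 1)
    ]
    if len(tissues) != n_tissues:
        raise ConfigError("tissue_names length must equal n_tissues")
    assignment = pd.Series("none", index=genes, name="module")
    gene_idx = {g: i for i, g in enumerate(genes)}
    for spec in module_spec:
        for g in spec.genes:
            if g not in gene_idx:
                raise ConfigError(f"module gene {g} not in atlas")
            if assignment[g] != "none":
                raise ConfigError(f"gene {g} assigned to two modules")
            assignment[g] = spec.name
        if spec.tissue not in tissues:
            raise ConfigError(f"module tissue {spec.tissue} not among tissues")

    libraries = []
    lib_tissue = []
    for t in tissues:
        for j in range(1, libs_per_tissue + 1):
            libraries.append(f"{t}_lib{j}")
            lib_tissue.append(t)
    design = pd.Series(lib_tissue, index=libraries, name="tissue")

    base = base_log_mean + base_log_sd * rng.normal(size=n_genes)
    mu = np.tile(base[:, None], (1, len(libraries)))
    for spec in module_spec:
        rows = [gene_idx[g] for g in spec.genes]
        cols = [i for i, t in enumerate(lib_tissue) if t == spec.tissue]
        # planted module genes are solidly expressed (baseline at or above
        # the atlas mean), as the canonical developmental genes they emulate
        mu[rows, :] = base_log_mean + np.abs(base[rows, None] - base_log_mean)
        mu[np.ix_(rows, cols)] += spec.strength
    mu = mu + noise_sd * rng.normal(size=mu.shape)
    lam = np.exp(mu)
    counts = rng.poisson(lam) if poisson else np.round(lam).astype(int)
    counts = pd.DataFrame(counts.astype(int), index=genes, columns=libraries)
    return counts, design, assignment


# ------------------------------------------------------------------- PPI


def simulate_ppi_network(
    n_nodes: int,
    attachment: int = 3,
    planted_module=(),
    seed: int = 0,
    node_names=None,
) -> nx.Graph:
    """Scale-free interaction network with a planted dense module.

    Preferential attachment (Barabasi-Albert, ``attachment`` edges per new
    node) gives the heavy-tailed degree distribution of real interactomes;
    the planted module's nodes are wired into a clique so they can later
    receive high heat and be recovered as a subnetwork.
    """
    names = list(node_names) if node_names is not None else gene_names(n_nodes)
    if len(names) != n_nodes:
        raise ConfigError("node_names length must equal n_nodes")
    planted = list(planted_module)
    if len(planted) > n_nodes:
        raise ConfigError("planted module larger than the network")
    unknown = set(planted) - set(names)
    if unknown:
        raise ConfigError(f"planted module nodes not in network: {sorted(unknown)[:5]}")
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(seed + _SEED_PPI))
    # shuffle the node -> name mapping: preferential attachment builds hubs
    # at the oldest nodes, and gene names must not encode degree
    rng = np.random.default_rng(seed + _SEED_PPI + 1)
    shuffled = [names[i] for i in rng.permutation(n_nodes)]
    g = nx.relabel_nodes(g, dict(enumerate(shuffled)))
    for i, u in enumerate(planted):
        for v in planted[i + 1 :]:
            g.add_edge(u, v)
    return g


# ------------------------------------------------------------------- CNV


def simulate_cnv_callsets(
    individuals,
    seed: int = 0,
    callers=("arrayCGH", "readdepth1", "readdepth2"),
    n_true_per_individual: float = 0.5,
    n_noise_per_caller: float = 1.0,
):
    """Small synthetic CNV call lists from several callers.

    True events (length > 100 kb) are reported by at least two callers with
    jittered breakpoints; noise calls are caller-private or too short.
    Returns ``(callsets, truth_calls)``.
    """
    from .cnv import CnvCall

    rng = np.random.default_rng(seed + 523)
    callsets = {c: [] for c in callers}
    truth = []
    for ind in individuals:
        for _ in range(rng.poisson(n_true_per_individual)):
            chrom = str(rng.integers(1, 23))
            start = int(rng.integers(1_000_000, 50_000_000))
            length = int(rng.integers(150_000, 2_000_000))
            state = "deletion" if rng.random() < 0.5 else "duplication"
            truth.append(CnvCall(chrom, start, start + length, state, ind, "truth"))
            support = rng.permutation(len(callers))[: rng.integers(2, len(callers) + 1)]
            for ci in support:
                jitter = int(rng.integers(-5_000, 5_000))
                callsets[callers[ci]].append(
                    CnvCall(chrom, start + jitter, start + length + jitter, state, ind, callers[ci])
                )
        for c in callers:
            for _ in range(rng.poisson(n_noise_per_caller / len(callers))):
                chrom = str(rng.integers(1, 23))
                start = int(rng.integers(1_000_000, 50_000_000))
                length = int(rng.integers(10_000, 90_000))
                state = "deletion" if rng.random() < 0.5 else "duplication"
                callsets[c].append(CnvCall(chrom, start, start + length, state, ind, c))
    return [callsets[c] for c in callers], truth
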