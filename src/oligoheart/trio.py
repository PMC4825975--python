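"""Rare-disease inheritance model for trio genotypes.

Variant calls are filtered on panel allele frequency, per-member read depth
and genotype quality, consequence class, and a gene blacklist; surviving
calls are classified into the three inheritance patterns of sporadic rare
disease — de novo, rare homozygous, and compound heterozygous in trans —
and collated per gene.  Phasing is by transmission: a variant heterozygous
in both parents has ambiguous origin and never supports a compound-het
call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PROTEIN_ALTERING, TrioCohort

log = logging.getLogger(__name__)

DEFAULT_MAF_MAX = 0.03
DEFAULT_DEPTH_MIN = 8
DEFAULT_QUALITY_MIN = 0.5

CALL_COLUMNS = [
    "individual",
    "family",
    "phenotype",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_id",
    "gene",
    "consequence",
    "maf",
    "gt_child",
    "gt_mother",
    "gt_father",
    "dp_child",
    "dp_mother",
    "dp_father",
    "q_child",
    "q_mother",
    "q_father",
]


class TrioDataError(ValueError):
    """Raised when pedigree and genotype data disagree."""


@dataclass(frozen=True)
class Blacklist:
    """Genes excluded from the inheritance model, with a provenance tag per
    gene (mutation-tolerant by RVIS percentile, or copy-number polymorphic)."""

    provenance: dict = field(default_factory=dict)

    VALID_TAGS = frozenset({"rvis_gt_90th", "cnv_polymorphic"})

    def __contains__(self, gene) -> bool:
        return gene in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)

    @classmethod
    def from_genes(cls, genes, tag: str = "rvis_gt_90th") -> "Blacklist":
        return cls(provenance={g: tag for g in genes})

    @classmethod
    def from_file(cls, path) -> "Blacklist":
        prov = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                prov[parts[0]] = parts[1] if len(parts) > 1 else "rvis_gt_90th"
        return cls(provenance=prov)


def cohort_to_calls(cohort: TrioCohort, phenotype: int | None = None) -> pd.DataFrame:
    """Flatten a trio cohort into one row per (proband, variant) where the
    proband carries at least one alternate allele (or has a missing
    genotype, so the missing-data handling in the filter is exercised)."""
    trios = cohort.trios
    if phenotype is not None:
        t_idx = np.flatnonzero(trios["phenotype"].to_numpy() == phenotype)
    else:
        t_idx = np.arange(len(trios))
    child = cohort.gt[:, t_idx, 0]
    s_i, t_i = np.nonzero((child >= 1) | (child == -1))
    t_orig = t_idx[t_i]
    sites = cohort.sites
    vid = (
        sites["chrom"].astype(str) + ":" + sites["pos"].astype(str) + ":" + sites["ref"] + ":" + sites["alt"]
    ).to_numpy()
    df = pd.DataFrame(
        {
            "individual": trios["child"].to_numpy()[t_orig],
            "family": trios["family"].to_numpy()[t_orig],
            "phenotype": trios["phenotype"].to_numpy()[t_orig],
            "chrom": sites["chrom"].to_numpy()[s_i],
            "pos": sites["pos"].to_numpy()[s_i],
            "ref": sites["ref"].to_numpy()[s_i],
            "alt": sites["alt"].to_numpy()[s_i],
            "variant_id": vid[s_i],
            "gene": sites["gene"].to_numpy()[s_i],
            "consequence": sites["consequence"].to_numpy()[s_i],
            "maf": sites["maf"].to_numpy()[s_i],
            "gt_child": cohort.gt[s_i, t_orig, 0],
            "gt_mother": cohort.gt[s_i, t_orig, 1],
            "gt_father": cohort.gt[s_i, t_orig, 2],
            "dp_child": cohort.dp[s_i, t_orig, 0],
            "dp_mother": cohort.dp[s_i, t_orig, 1],
            "dp_father": cohort.dp[s_i, t_orig, 2],
            "q_child": cohort.qual[s_i, t_orig, 0],
            "q_mother": cohort.qual[s_i, t_orig, 1],
            "q_father": cohort.qual[s_i, t_orig, 2],
        }
    )
    return df[CALL_COLUMNS]


def filter_variants(
    calls: pd.DataFrame,
    maf_max: float = DEFAULT_MAF_MAX,
    depth_min: int = DEFAULT_DEPTH_MIN,
    quality_min: float = DEFAULT_QUALITY_MIN,
    allowed_consequences=PROTEIN_ALTERING,
    blacklist: Blacklist | None = None,
) -> pd.DataFrame:
    """Apply the rare-variant filters; all thresholds are inclusive.

    A call is retained iff its panel MAF is absent or <= ``maf_max``, every
    trio member has depth >= ``depth_min`` and quality >= ``quality_min``,
    the consequence is protein-altering, and the gene is not blacklisted.
    Calls with a missing genotype in any member are dropped with a logged
    reason, never an exception.  Input order is preserved and the filter is
    idempotent.
    """
    for thr in (maf_max, depth_min, quality_min):
        if not math.isfinite(thr):
            raise ValueError("filter thresholds must be finite")
    missing = (
        (calls["gt_child"] < 0) | (calls["gt_mother"] < 0) | (calls["gt_father"] < 0)
    )
    if missing.any():
        log.info("dropped %d calls: reason=missing_genotype", int(missing.sum()))
    rare = calls["maf"].isna() | (calls["maf"] <= maf_max)
    deep = (
        (calls["dp_child"] >= depth_min)
        & (calls["dp_mother"] >= depth_min)
        & (calls["dp_father"] >= depth_min)
    )
    confident = (
        (calls["q_child"] >= quality_min)
        & (calls["q_mother"] >= quality_min)
        & (calls["q_father"] >= quality_min)
    )
    altering = calls["consequence"].isin(set(allowed_consequences))
    keep = ~missing & rare & deep & confident & altering
    if blacklist is not None and len(blacklist):
        listed = calls["gene"].map(lambda g: g in blacklist)
        if listed.any():
            log.info("dropped %d calls: reason=blacklisted_gene", int(listed.sum()))
        keep &= ~listed
    return calls[keep]


def classify_inheritance(calls: pd.DataFrame, pedigree: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify filtered calls into inheritance events.

    de novo: proband carries an alternate allele absent from both parents.
    rare homozygous: proband homozygous alternate with each parent carrying
    exactly one alternate allele.  compound heterozygous: two heterozygous
    variants in the same gene, one of unambiguous maternal and one of
    unambiguous paternal origin (in trans); a variant whose origin is
    ambiguous (both parents carriers) never contributes.  Output is one row
    per event with columns individual, gene, mode, variant_ids; invariant
    to the input ordering of calls.
    """
    if pedigree is not None:
        known = set(pedigree["child"])
        strays = set(calls["individual"]) - known
        if strays:
            raise TrioDataError(
                f"calls reference individuals absent from the pedigree: {sorted(strays)[:5]}"
            )
    calls = calls.sort_values(["individual", "gene", "chrom", "pos", "ref", "alt"], kind="stable")
    c, m, f = (calls[k].to_numpy() for k in ("gt_child", "gt_mother", "gt_father"))

    denovo = (c >= 1) & (m == 0) & (f == 0)
    rarehom = (c == 2) & (m == 1) & (f == 1)
    het = c == 1
    maternal = het & (m >= 1) & (f == 0)
    paternal = het & (f >= 1) & (m == 0)

    records = []
    for mask, mode in ((denovo, "de_novo"), (rarehom, "rare_homozygous")):
        sub = calls[mask]
        for r in sub.itertuples():
            records.append((r.individual, r.gene, mode, r.variant_id))

    ch = calls[maternal | paternal].assign(origin=np.where(maternal[maternal | paternal], "m", "p"))
    for (ind, gene), grp in ch.groupby(["individual", "gene"], sort=True):
        mats = grp[grp.origin == "m"]["variant_id"].tolist()
        pats = grp[grp.origin == "p"]["variant_id"].tolist()
        for vm in mats:
            for vp in pats:
                records.append((ind, gene, "compound_het", f"{vm},{vp}"))

    events = pd.DataFrame(records, columns=["individual", "gene", "mode", "variant_ids"])
    return events.sort_values(["individual", "gene", "mode", "variant_ids"], kind="stable").reset_index(
        drop=True
    )


def collate_by_gene(events: pd.DataFrame):
    """Gene -> events mapping plus summary counts.

    Because the variant-counting convention for compound-heterozygous pairs
    is genuinely ambiguous (a pair is one event but two variants), the
    summary reports both: ``n_variants_pairs_as_two`` counts each member of
    a pair, ``n_variants_events`` counts one per event.  Genes are counted
    once per individual regardless of how many pairs they contain.
    """
    if len(events) == 0:
        return {}, {
            "n_events": 0,
            "n_genes": 0,
            "n_individuals": 0,
            "n_variants_pairs_as_two": 0,
            "n_variants_events": 0,
            "n_gene_individual_pairs": 0,
        }
    by_gene = {g: grp.reset_index(drop=True) for g, grp in events.groupby("gene", sort=True)}
    distinct_variants = set()
    for r in events.itertuples():
        for v in r.variant_ids.split(","):
            distinct_variants.add((r.individual, v))
    summary = {
        "n_events": int(len(events)),
        "n_genes": int(events["gene"].nunique()),
        "n_individuals": int(events["individual"].nunique()),
        "n_variants_pairs_as_two": len(distinct_variants),
        "n_variants_events": int(len(events)),
        "n_gene_individual_pairs": int(events.groupby(["gene", "individual"]).ngroups),
    }
    return by_gene, summary


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def qc_statistics(calls: pd.DataFrame) -> dict:
    """Ti/Tv ratio over proband SNVs and the transmission-phasable fraction
    of proband heterozygous genotypes.

    Transitions are purine<->purine or pyrimidine<->pyrimidine substitutions.
    A heterozygous genotype is phased when exactly one parental origin is
    consistent with transmission; both-parents-heterozygous sites are
    unphasable.  Sentinels: Ti/Tv is +inf with zero transversions, the
    phased fraction is NaN with no heterozygous genotypes.
    """
    snv = calls[(calls["ref"].str.len() == 1) & (calls["alt"].str.len() == 1)]
    snv = snv[snv["gt_child"] >= 1]
    ti = sum(
        1
        for r, a in zip(snv["ref"], snv["alt"])
        if (r in _PURINES) == (a in _PURINES)
    )
    tv = len(snv) - ti
    titv = math.inf if tv == 0 else ti / tv

    het = calls[calls["gt_child"] == 1]
    if len(het) == 0:
        phased = float("nan")
    else:
        m = het["gt_mother"].to_numpy()
        f = het["gt_father"].to_numpy()
        maternal_ok = (m >= 1) & (f <= 1)  # mother can give alt, father a ref
        paternal_ok = (f >= 1) & (m <= 1)
        resolved = maternal_ok ^ paternal_ok
        phased = float(resolved.mean())
    return {
        "titv_ratio": titv,
        "phased_fraction": phased,
        "n_snvs": int(len(snv)),
        "n_transitions": int(ti),
        "n_transversions": int(tv),
        "n_het_genotypes": int(len(het)),
    }


def incidence_matrix(events: pd.DataFrame, individuals, genes) -> np.ndarray:
    """Boolean individuals x genes incidence of qualifying events, the
    carrier bookkeeping behind the Fisher and Monte-Carlo contrasts."""
    ind_idx = {x: i for i, x in enumerate(individuals)}
    gene_idx = {g: j for j, g in enumerate(genes)}
    inc = np.zeros((len(ind_idx), len(gene_idx)), dtype=bool)
    for r in events.itertuples():
        if r.individual in ind_idx and r.gene in gene_idx:
            inc[ind_idx[r.individual], gene_idx[r.gene]] = True
    return inc
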