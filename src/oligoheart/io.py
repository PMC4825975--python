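"""VCF 4.2 / PED emission and parsing for trio cohorts.

The emitted VCF carries GT, DP and a scalar genotype-quality field AVR in
[0, 1] per sample, with the gene symbol, consequence class and panel MAF in
INFO.  Genotypes are written unphased; parental origin is inferred
downstream by transmission.  Reading goes through cyvcf2 so real files are
accepted wherever synthetic ones are.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TrioCohort

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Reference-panel minor allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AVR,Number=1,Type=Float,Description="Genotype quality score in [0,1]">
"""

_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_trio_vcf(cohort: TrioCohort, vcf_path, ped_path) -> None:
    """Write a trio cohort as VCF 4.2 plus a 6-column PED file."""
    samples = []
    for t in cohort.trios.itertuples():
        samples.extend([t.child, t.mother, t.father])
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(cohort.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        n_trios = cohort.n_trios
        for s in range(cohort.n_sites):
            row = cohort.sites.iloc[s]
            info = f"GENE={row.gene};CSQ={row.consequence};MAF={row.maf:.6g}"
            fields = [
                str(row.chrom),
                str(row.pos),
                ".",
                row.ref,
                row.alt,
                ".",
                "PASS",
                info,
                "GT:DP:AVR",
            ]
            for t in range(n_trios):
                for m in range(3):
                    fields.append(
                        f"{_GT_STR[int(cohort.gt[s, t, m])]}:{int(cohort.dp[s, t, m])}:"
                        f"{cohort.qual[s, t, m]:.4f}"
                    )
            fh.write("\t".join(fields) + "\n")
    write_ped(cohort.trios, ped_path)


def write_ped(trios: pd.DataFrame, path) -> None:
    """6-column PED: family, individual, father, mother, sex, phenotype."""
    with open(path, "w") as fh:
        for t in trios.itertuples():
            fh.write(f"{t.family}\t{t.father}\t0\t0\t1\t1\n")
            fh.write(f"{t.family}\t{t.mother}\t0\t0\t2\t1\n")
            fh.write(f"{t.family}\t{t.child}\t{t.father}\t{t.mother}\t0\t{t.phenotype}\n")


def read_ped(path) -> pd.DataFrame:
    """Reconstruct the trio table (one row per child with both parents)."""
    ped = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family", "individual", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    kids = ped[(ped.father != "0") & (ped.mother != "0")]
    return pd.DataFrame(
        {
            "family": kids.family.to_numpy(),
            "child": kids.individual.to_numpy(),
            "mother": kids.mother.to_numpy(),
            "father": kids.father.to_numpy(),
            "phenotype": kids.phenotype.astype(int).to_numpy(),
        }
    )


def read_trio_vcf(vcf_path, ped_path) -> TrioCohort:
    """Parse a trio VCF + PED back into the in-memory cohort container."""
    from cyvcf2 import VCF

    trios = read_ped(ped_path)
    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    member_cols = np.array(
        [[sample_idx[t.child], sample_idx[t.mother], sample_idx[t.father]] for t in trios.itertuples()]
    )
    rows, gts, dps, quals = [], [], [], []
    for v in vcf:
        info_maf = v.INFO.get("MAF")
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "maf": float(info_maf) if info_maf is not None else np.nan,
                "gene": v.INFO.get("GENE"),
                "consequence": v.INFO.get("CSQ"),
            }
        )
        alleles = np.array(v.genotypes, dtype=int)[:, :2]
        gt = np.where((alleles < 0).any(axis=1), -1, alleles.clip(min=0).sum(axis=1))
        gts.append(gt[member_cols])
        dps.append(np.asarray(v.format("DP")).reshape(-1)[member_cols])
        quals.append(np.asarray(v.format("AVR")).reshape(-1)[member_cols])
    vcf.close()
    sites = pd.DataFrame(rows)
    return TrioCohort(
        sites=sites,
        trios=trios,
        gt=np.array(gts, dtype=np.int8),
        dp=np.array(dps, dtype=np.int16),
        qual=np.array(quals, dtype=np.float32),
    )


def write_singleton_matrix(cohort, geno_path, variant_path) -> None:
    """Genotype dosage matrix (individuals x variants) and variant table."""
    pd.DataFrame(
        cohort.G,
        index=cohort.individuals,
        columns=[f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}" for r in cohort.variants.itertuples()],
    ).assign(phenotype=cohort.y).to_csv(geno_path, sep="\t")
    cohort.variants.to_csv(variant_path, sep="\t", index=False)


def read_singleton_matrix(geno_path, variant_path):
    from .simulate import SingletonCohort

    df = pd.read_csv(geno_path, sep="\t", index_col=0)
    y = df.pop("phenotype").to_numpy()
    variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    return SingletonCohort(
        G=df.to_numpy(dtype=np.int8),
        y=y,
        variants=variants,
        individuals=list(df.index),
    )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_edge_list(path):
    """Two-column TSV edge list into an undirected simple graph."""
    import networkx as nx

    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split("\t")[:2]
            if u != v:
                g.add_edge(u, v)
    return g


def write_edge_list(graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")
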