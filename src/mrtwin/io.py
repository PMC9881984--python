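"""Readers and writers for the plain-text interchange formats.

The native on-disk layout is script-friendly TSV:

* genotypes — one row per individual, first column ``individual_id``,
  remaining columns additive dosages (0/1/2) headed by SNP ids;
* pedigree — ``family_id  individual_id  father_id  mother_id  role`` with
  role in {offspring, father, mother, sibling} and ``0`` for a missing
  parent id (FAM-style);
* phenotypes — ``individual_id  exposure  outcome``;
* summary statistics — one row per SNP with the canonical column names
  ``snp_id, beta_exposure, se_exposure, p_exposure, beta_outcome,
  se_outcome`` (common aliases from other MR tools are accepted);
* a JSON sidecar recording the simulation config and seed.

A minimal unphased VCF writer/reader is provided for interoperability; GT
fields (phased or not) are collapsed to additive dosage and multi-allelic
records are skipped with a warning.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, SchemaError
from .simulate import PopSimConfig, SimDataset, simulate_dataset
from .twins import FamilySet, GENOTYPE_DTYPE

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_pedigree", "read_pedigree",
    "write_summary_stats", "read_summary_stats",
    "write_vcf", "read_vcf",
    "write_dataset", "read_families", "make_fixtures",
]

MISSING = -1  # sentinel for missing genotype dosage

# Aliases used by common MR toolchains (e.g. TwoSampleMR-style exports).
SUMMARY_ALIASES = {
    "snp": "snp_id", "SNP": "snp_id", "rsid": "snp_id",
    "beta.exposure": "beta_exposure", "se.exposure": "se_exposure",
    "pval.exposure": "p_exposure", "pval_exposure": "p_exposure",
    "beta.outcome": "beta_outcome", "se.outcome": "se_outcome",
    "pval.outcome": "p_outcome", "pval_outcome": "p_outcome",
    "samplesize.exposure": "n",
}
REQUIRED_SUMMARY = [
    "snp_id", "beta_exposure", "se_exposure", "p_exposure", "beta_outcome", "se_outcome",
]


def write_genotypes(path, genotypes, individual_ids, snp_ids) -> None:
    df = pd.DataFrame(np.asarray(genotypes), columns=list(snp_ids))
    df.insert(0, "individual_id", list(individual_ids))
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, fmt: str = "tsv_additive"):
    """Read a genotype matrix; returns (matrix, snp_ids, individual_ids)."""
    if fmt == "vcf":
        return read_vcf(path)
    if fmt != "tsv_additive":
        raise SchemaError(f"unknown genotype format {fmt!r}")
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise SchemaError("genotype TSV must have an individual_id column")
    ids = df["individual_id"].astype(str).tolist()
    snp_ids = [c for c in df.columns if c != "individual_id"]
    mat = df[snp_ids].to_numpy()
    if not np.all(np.isin(mat[mat != MISSING], [0, 1, 2])):
        raise SchemaError("genotype dosages must be integers in {0,1,2} (or -1 for missing)")
    return mat.astype(GENOTYPE_DTYPE), snp_ids, ids


def write_phenotypes(path, individual_ids, exposure, outcome) -> None:
    pd.DataFrame(
        {"individual_id": list(individual_ids), "exposure": exposure, "outcome": outcome}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("individual_id", "outcome"):
        if c not in df.columns:
            raise SchemaError(f"phenotype TSV lacks required column {c!r}")
    df["individual_id"] = df["individual_id"].astype(str)
    return df


def write_pedigree(path, records: pd.DataFrame) -> None:
    cols = ["family_id", "individual_id", "father_id", "mother_id", "role"]
    records[cols].to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "individual_id", "father_id", "mother_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"pedigree TSV lacks column(s): {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        raise SchemaError("individual ids must be unique within the pedigree file")
    return df


def write_summary_stats(path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    """Read and validate a summary-statistics TSV; extra columns pass through."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={k: v for k, v in SUMMARY_ALIASES.items() if k in df.columns})
    missing = [c for c in REQUIRED_SUMMARY if c not in df.columns]
    if missing:
        raise SchemaError(f"summary statistics lack required column(s): {missing}")
    for c in ("se_exposure", "se_outcome"):
        if (df[c] <= 0).any():
            raise SchemaError(f"{c} must be positive for every SNP")
    if ((df["p_exposure"] <= 0) | (df["p_exposure"] > 1)).any():
        raise SchemaError("p_exposure must lie in (0, 1]")
    df["snp_id"] = df["snp_id"].astype(str)
    return df


# --- minimal plain-text VCF support (GT only, biallelic) -------------------

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, genotypes, individual_ids, snp_ids) -> None:
    """Write unphased biallelic records, one per SNP, GT format only."""
    g = np.asarray(genotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in individual_ids) + "\n")
        for j, snp in enumerate(snp_ids):
            calls = "\t".join(_VCF_GT[int(v)] for v in g[:, j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def _gt_to_dosage(gt: str) -> int:
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles:
        return MISSING
    return sum(int(a) for a in alleles)


def read_vcf(path):
    """Read a plain-text VCF into (matrix, snp_ids, individual_ids).

    Multi-allelic records are skipped with a warning; GT separators may be
    ``/`` or ``|`` (phasing is irrelevant for additive coding).
    """
    snp_ids: list[str] = []
    rows: list[list[int]] = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if "," in fields[4]:
                warnings.warn(f"skipping multi-allelic record {fields[2]}", stacklevel=2)
                continue
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            rows.append([_gt_to_dosage(s.split(":")[gt_idx]) for s in fields[9:]])
            snp_ids.append(fields[2])
    if not samples:
        raise SchemaError("VCF has no #CHROM header line")
    mat = np.asarray(rows, dtype=GENOTYPE_DTYPE).T  # individuals x SNPs
    return mat, snp_ids, samples


# --- dataset-level helpers -------------------------------------------------

def write_dataset(dataset: SimDataset, outdir) -> dict[str, Path]:
    """Serialize a simulated dataset to the native TSV layout + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_fam = dataset.families.n_families
    fam = dataset.families

    ext_ids = [f"ext{i}" for i in range(dataset.external_genotypes.shape[0])]
    off_ids = [f"fam{i}_off" for i in range(n_fam)]
    fa_ids = [f"fam{i}_fa" for i in range(n_fam)]
    mo_ids = [f"fam{i}_mo" for i in range(n_fam)]

    paths = {
        "external_genotypes": outdir / "external_genotypes.tsv",
        "family_genotypes": outdir / "family_genotypes.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "external_phenotypes": outdir / "external_phenotypes.tsv",
        "family_phenotypes": outdir / "family_phenotypes.tsv",
        "config": outdir / "config.json",
    }
    write_genotypes(paths["external_genotypes"], dataset.external_genotypes, ext_ids,
                    dataset.snp_ids)
    fam_geno = np.vstack([fam.offspring, fam.parent1, fam.parent2])
    write_genotypes(paths["family_genotypes"], fam_geno, off_ids + fa_ids + mo_ids,
                    dataset.snp_ids)
    ped = pd.DataFrame(
        {
            "family_id": [f"fam{i}" for i in range(n_fam)] * 3,
            "individual_id": off_ids + fa_ids + mo_ids,
            "father_id": fa_ids + ["0"] * (2 * n_fam),
            "mother_id": mo_ids + ["0"] * (2 * n_fam),
            "role": ["offspring"] * n_fam + ["father"] * n_fam + ["mother"] * n_fam,
        }
    )
    write_pedigree(paths["pedigree"], ped)
    write_phenotypes(paths["external_phenotypes"], ext_ids, dataset.external_exposure,
                     dataset.external_outcome)
    write_phenotypes(paths["family_phenotypes"], off_ids, fam.exposures, fam.outcomes)
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(dataset.config), fh, indent=2)
    return paths


def read_families(pedigree_path, genotype_path, phenotype_path, design: str | None = None,
                  fmt: str = "tsv_additive") -> FamilySet:
    """Assemble a FamilySet from pedigree + genotype + phenotype files.

    The design is inferred from the pedigree roles (trio if both parents
    present, duo for one, sibling for parentless sibships) unless forced.
    """
    ped = read_pedigree(pedigree_path)
    geno, snp_ids, ids = read_genotypes(genotype_path, fmt=fmt)
    pheno = read_phenotypes(phenotype_path)
    row_of = {i: k for k, i in enumerate(ids)}
    out_of = dict(zip(pheno["individual_id"], pheno["outcome"]))
    exp_of = (
        dict(zip(pheno["individual_id"], pheno["exposure"]))
        if "exposure" in pheno.columns else {}
    )

    offspring, p1, p2, sibs, outs, exps, fam_ids = [], [], [], [], [], [], []
    designs = set()
    for fam_id, group in ped.groupby("family_id", sort=True):
        roles = dict(zip(group["role"], group["individual_id"]))
        sib_rows = group.loc[group["role"] == "sibling", "individual_id"].tolist()
        if "offspring" in roles:
            child = roles["offspring"]
        elif sib_rows:
            child = sib_rows[0]
        else:
            raise SchemaError(f"family {fam_id} has no offspring or sibling rows")
        for ind in group["individual_id"]:
            if ind not in row_of:
                raise AlignmentError(f"individual {ind} missing from genotype file")
        if child not in out_of:
            raise AlignmentError(f"no phenotype row for index individual {child}")

        if "father" in roles and "mother" in roles:
            designs.add("trio")
            p1.append(geno[row_of[roles["father"]]])
            p2.append(geno[row_of[roles["mother"]]])
        elif "father" in roles or "mother" in roles:
            designs.add("duo")
            parent = roles.get("father", roles.get("mother"))
            p1.append(geno[row_of[parent]])
        else:
            designs.add("sibling")
            members = [child] + [s for s in sib_rows if s != child]
            sibs.append(np.vstack([geno[row_of[s]] for s in members]))
        offspring.append(geno[row_of[child]])
        outs.append(out_of[child])
        exps.append(exp_of.get(child, np.nan))
        fam_ids.append(str(fam_id))

    if len(designs) != 1:
        raise SchemaError(f"mixed family designs in one pedigree: {sorted(designs)}")
    inferred = designs.pop()
    if design is not None and design != inferred:
        raise SchemaError(f"pedigree implies design {inferred!r}, not {design!r}")
    exposures = np.asarray(exps, dtype=float)
    return FamilySet(
        design=inferred,
        offspring=np.vstack(offspring),
        outcomes=np.asarray(outs, dtype=float),
        parent1=np.vstack(p1) if p1 else None,
        parent2=np.vstack(p2) if p2 else None,
        siblings=sibs if sibs else None,
        snp_ids=snp_ids,
        family_ids=fam_ids,
        exposures=exposures if np.isfinite(exposures).all() else None,
    )


def make_fixtures(outdir, seed: int = 0, beta_causal_EO: float = 0.0) -> dict[str, Path]:
    """Write a small on-disk trio dataset for tests and examples.

    20 families, 10 SNPs (5 causal), and summary statistics computed from a
    2000-sample external cohort simulated under the same architecture.
    """
    from .gwas import summary_stats as _summary

    config = PopSimConfig(
        n_external=2000, n_families=20, m_snps=10, m_causal=5,
        beta_causal_EO=beta_causal_EO, seed=seed,
    )
    data = simulate_dataset(config)
    paths = write_dataset(data, outdir)
    stats = _summary(data.external_genotypes, data.external_exposure,
                     data.external_outcome, snp_ids=data.snp_ids)
    stats_path = Path(outdir) / "summary_stats.tsv"
    write_summary_stats(stats_path, stats)
    paths["summary_stats"] = stats_path
    return paths
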