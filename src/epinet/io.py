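"""Readers and writers for genotype, phenotype and ground-truth files.

Genotypes come in as biallelic VCF (GT parsed to counted-ALT dosage,
``./.`` mapped to MISSING) or as a TSV dosage matrix, in both cases
joined against a panel annotation TSV (snp_id, gene, chromosome,
counted_allele).  Phenotypes are plain TSV with named indicator and
covariate columns.  All writers emit text formats that round-trip
through the package's own readers.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, PANEL_COLUMNS, GenotypeMatrix, PhenotypeTable
from .simulate import TruthRecord

# ---------------------------------------------------------------------------
# panel annotation
# ---------------------------------------------------------------------------


def read_panel(path) -> pd.DataFrame:
    """Panel annotation TSV -> DataFrame indexed by snp_id."""
    panel = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel file {path} lacks columns {missing}")
    if panel["snp_id"].duplicated().any():
        dupes = panel.loc[panel["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id in panel: {dupes}")
    return panel.set_index("snp_id")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, panel_path) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV plus a panel annotation.

    VCF records must be biallelic; multi-allelic records raise a named
    error.  Every variant must appear in the panel (by snp_id).
    """
    path = Path(path)
    panel = read_panel(panel_path)
    if path.suffix.lower() == ".vcf":
        subjects, snp_ids, dosages = _read_vcf(path)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        subjects = [str(s) for s in frame.index]
        snp_ids = [str(c) for c in frame.columns]
        dosages = frame.to_numpy(dtype=float)
        dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    absent = [s for s in snp_ids if s not in panel.index]
    if absent:
        raise ValueError(f"panel annotation missing SNPs: {absent}")
    return GenotypeMatrix(subjects, panel.loc[snp_ids], np.asarray(dosages))


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"({var.ID}); only biallelic SNPs are supported")
        snp_ids.append(var.ID)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.full(len(subjects), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        columns.append(col)
    if len(set(snp_ids)) != len(snp_ids):
        dupes = sorted({s for s in snp_ids if snp_ids.count(s) > 1})
        raise ValueError(f"duplicate snp_id in VCF: {dupes}")
    return subjects, snp_ids, np.column_stack(columns) if columns else \
        np.empty((len(subjects), 0), dtype=np.int8)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_OTHER_ALLELE = {"A": "C", "C": "A", "G": "A", "T": "A"}


def write_genotypes_vcf(G: GenotypeMatrix, path) -> Path:
    """Write dosages as a minimal biallelic VCF (ALT = counted allele)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = []
    for snp in G.snp_ids:
        c = str(G.panel.loc[snp].get("chromosome", "1"))
        if c not in chroms:
            chroms.append(c)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.subjects))
    for j, snp in enumerate(G.snp_ids):
        row = G.panel.loc[snp]
        alt = str(row.get("counted_allele", "G"))
        ref = _OTHER_ALLELE.get(alt, "A")
        gts = "\t".join(_GT[int(d)] for d in G.dosages[:, j])
        lines.append(f"{row.get('chromosome', '1')}\t{(j + 1) * 1000}\t{snp}"
                     f"\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_genotypes_tsv(G: GenotypeMatrix, path) -> Path:
    frame = G.to_frame().astype(float)
    frame[frame == MISSING] = np.nan
    frame.to_csv(path, sep="\t", na_rep="NA")
    return Path(path)


def write_panel(G: GenotypeMatrix, path) -> Path:
    panel = G.panel.copy()
    for col in PANEL_COLUMNS[1:]:
        if col not in panel.columns:
            panel[col] = {"chromosome": "1", "counted_allele": "G"}.get(col, "")
    panel.index.name = "snp_id"
    panel[list(PANEL_COLUMNS[1:])].to_csv(path, sep="\t")
    return Path(path)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(pheno: PhenotypeTable, path) -> Path:
    pheno.data.to_csv(path, sep="\t", na_rep="NA")
    return Path(path)


def read_phenotypes(path, indicators, covariates) -> PhenotypeTable:
    data = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return PhenotypeTable(data, list(indicators), list(covariates))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_truth(truth: TruthRecord, path) -> Path:
    """Ground-truth record as a documented key-value + TSV text file.

    Header lines are ``key=value`` (scenario scalars and the analytic
    expected variance of each planted effect); the body is a TSV of
    per-subject true labels and gating probabilities.
    """
    path = Path(path)
    sc = truth.scenario
    head = [f"n_subjects={sc.n_subjects}", f"k_true={sc.n_classes}",
            f"seed={sc.seed}", f"noise_sd={sc.noise_sd}"]
    for i, eff in enumerate(sc.planted_effects):
        head.append(
            f"effect_{i}={eff.component}:{eff.snp_a}:{eff.snp_b or ''}"
            f":beta={eff.beta}:class={eff.target_class}"
            f":expected_variance={truth.expected_variance[i]:.10g}")
    K = truth.class_probs.shape[1]
    body = pd.DataFrame(
        {"true_class": truth.labels,
         **{f"prob_{k}": truth.class_probs[:, k] for k in range(K)}})
    with open(path, "w") as fh:
        for line in head:
            fh.write(f"# {line}\n")
        body.to_csv(fh, sep="\t", index=False)
    return path


def read_truth(path) -> tuple[dict, pd.DataFrame]:
    """Parse a truth file back into (header dict, per-subject table)."""
    meta, rows = {}, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, val = line[2:].strip().partition("=")
                meta[key] = val
            else:
                rows.append(line)
    from io import StringIO

    table = pd.read_csv(StringIO("".join(rows)), sep="\t")
    return meta, table


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or TOML run configuration into a plain dict."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    raise ValueError(f"unsupported config format: {path.suffix}")
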