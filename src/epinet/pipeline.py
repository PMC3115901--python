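"""End-to-end driver: partition -> per-stratum scans -> networks -> report.

The pipeline chains the latent-profile partition of the phenotype table,
the per-subpopulation two-locus epistasis scans for each trait (with the
Bonferroni threshold derived from the pair, subpopulation and trait
counts), the gene-network construction per stratum, the merged network,
and an optional core-network subtraction.  Every exclusion is logged as
one machine-readable record, and identical inputs plus seed reproduce
the output bundle byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epistasis import bonferroni_threshold, scan_subpopulation
from .io import load_config
from .mixture import LatentProfileModel, class_diagnostics, select_model
from .network import GeneNetwork, build_gene_network, merge_networks, \
    read_network, subtract_network, write_network
from .panel import GenotypeMatrix, PhenotypeTable


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs, file paths included."""

    geno_path: str
    panel_path: str
    pheno_path: str
    indicators: list
    covariates: list
    k_range: list
    traits: list | None = None       # default: the indicators
    alpha: float = 0.05
    curation: str = "max-edge"
    seed: int = 0
    min_stratum: int = 20
    margin: float = 2.0
    n_restarts: int = 20
    factor: bool = False
    core_network_path: str | None = None
    thresholds: tuple = (90.0, 140.0)
    out_dir: str = "epinet_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.traits is None:
            self.traits = list(self.indicators)
        bad = [t for t in self.traits if t not in self.indicators]
        if bad:
            raise ValueError(f"traits not among the indicators: {bad}")
        if not self.k_range:
            raise ValueError("k_range must be non-empty")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(**load_config(path))

    def digest(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class PipelineReport:
    """In-memory handles to everything the pipeline produced."""

    config: RunConfig
    selection_table: pd.DataFrame
    partition: "pd.DataFrame"
    scans: dict                     # (trait, subpop) -> ScanResult
    networks: dict                  # (trait, subpop) -> GeneNetwork
    merged: GeneNetwork
    subtracted: GeneNetwork | None
    summary: pd.DataFrame
    stratum_table: pd.DataFrame
    alpha_star: float
    out_dir: Path


class PipelineError(RuntimeError):
    """A stage failure, naming the stage; partial outputs stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", lineterminator="\n", **kw)


def run_pipeline(config: RunConfig, G: GenotypeMatrix | None = None,
                 pheno: PhenotypeTable | None = None) -> PipelineReport:
    """Execute the full two-step analysis and persist the report bundle.

    ``G`` and ``pheno`` may be passed directly (e.g. fresh from the
    simulator); otherwise they are read from the configured paths.
    Deterministic given the config seed.
    """
    from .io import read_genotypes, read_phenotypes

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _flush_log(log, out)
                    raise PipelineError(name, exc) from exc
                return False
        return _Ctx()

    with _stage("read-inputs"):
        if G is None:
            G = read_genotypes(config.geno_path, config.panel_path)
        if pheno is None:
            pheno = read_phenotypes(config.pheno_path, config.indicators,
                                    config.covariates)
        # harmonize subject order genotype <-> phenotype
        shared = [s for s in pheno.subjects if s in set(G.subjects)]
        dropped = len(pheno.subjects) - len(shared)
        if dropped:
            log.append({"stage": "read-inputs", "event": "subjects-dropped",
                        "reason": "no-genotype", "n": dropped})
        if not shared:
            raise ValueError("no shared subjects between genotype and "
                             "phenotype tables")
        G = G.take_subjects(shared)
        pheno = PhenotypeTable(pheno.data.loc[shared], pheno.indicators,
                               pheno.covariates)

    with _stage("partition"):
        keep = pheno.complete_cases()
        if (~keep).any():
            log.append({"stage": "partition", "event": "subjects-dropped",
                        "reason": "incomplete-phenotype",
                        "n": int((~keep).sum())})
        model = LatentProfileModel.from_phenotypes(pheno, factor=config.factor)
        best, selection = select_model(
            model, config.k_range, margin=config.margin,
            n_restarts=config.n_restarts, seed=config.seed)
        diag = class_diagnostics(best)
        used_subjects = [s for s, k in zip(pheno.subjects, keep) if k]
        partition = diag.to_frame(used_subjects)
        _write_tsv(selection, out / "selection.tsv", index=False)
        _write_tsv(partition, out / "partition.tsv")
        _write_tsv(diag.correlations, out / "class_correlations.tsv",
                   index=False)
        _write_tsv(diag.normality, out / "class_normality.tsv", index=False)

    with _stage("scan"):
        K = best.n_classes
        n_pairs = G.n_snps * (G.n_snps - 1) // 2
        alpha_star = bonferroni_threshold(config.alpha, n_pairs, K,
                                          len(config.traits))
        G_used = G.take_subjects(used_subjects)
        modal = partition["modal_class"].to_numpy()
        scans = {}
        for trait in config.traits:
            y = pheno.data.loc[used_subjects, trait].to_numpy(dtype=float)
            for k in range(K):
                members = np.flatnonzero(modal == k)
                scans[(trait, k)] = scan_subpopulation(
                    y, G_used, members, alpha_star, trait_name=trait,
                    subpop_id=k, min_stratum=config.min_stratum, log=log)
        for (trait, k), res in scans.items():
            _write_tsv(res.table, out / f"scan_{trait}_class{k}.tsv",
                       index=False)
            _write_tsv(res.stratum_qc, out / f"qc_{trait}_class{k}.tsv")

    with _stage("network"):
        genes = sorted(set(G.panel["gene"]))
        networks = {key: build_gene_network(res, curation=config.curation,
                                            genes=genes)
                    for key, res in scans.items()}
        merged = merge_networks(list(networks.values()))
        subtracted = None
        if config.core_network_path:
            core = read_network(config.core_network_path, "tsv", genes=genes)
            subtracted = subtract_network(merged, core)
        for (trait, k), net in networks.items():
            write_network(net, out / f"network_{trait}_class{k}.tsv", "tsv")
        write_network(merged, out / "network_merged.tsv", "tsv")
        write_network(merged, out / "network_merged.net", "pajek")
        write_network(merged, out / "network_merged.graphml", "graphml")
        if subtracted is not None:
            write_network(subtracted, out / "network_subtracted.tsv", "tsv")

    with _stage("summarize"):
        summary, union = summarize_scan(list(scans.values()))
        stratum_table = _stratum_table(pheno, used_subjects, modal, K,
                                       config.thresholds)
        _write_tsv(summary, out / "summary_interactions.tsv", index=False)
        _write_tsv(union, out / "summary_union.tsv", index=False)
        _write_tsv(stratum_table, out / "summary_strata.tsv", index=False)
        manifest = {
            "epinet_version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "n_subjects": len(used_subjects),
            "n_snps": G.n_snps,
            "selected_k": int(K),
            "alpha_star": alpha_star,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n")
        _flush_log(log, out)

    return PipelineReport(config, selection, partition, scans, networks,
                          merged, subtracted, summary, stratum_table,
                          alpha_star, out)


def _flush_log(log: list, out: Path) -> None:
    with open(out / "exclusions.jsonl", "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def summarize_scan(results) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum interaction counts plus cross-stratum union counts.

    The per-stratum rows give subject counts, significant-interaction
    counts, the fraction of possible pairs and the spread of relative
    genetic values among the significant set; the union table counts
    distinct significant pairs pooled over strata per trait.
    """
    if not results:
        raise ValueError("no scan results to summarize")
    rows = []
    union: dict[str, set] = {}
    for res in results:
        sig = res.significant
        rel = sig["relative_epistasis"] if not sig.empty else pd.Series(dtype=float)
        rows.append({
            "subpopulation": res.subpop_id, "trait": res.trait_name,
            "n_subjects": res.n_subjects, "n_possible": res.n_possible,
            "n_significant": res.n_significant,
            "fraction_significant": res.fraction_significant,
            "rel_var_min": rel.min() if len(rel) else np.nan,
            "rel_var_max": rel.max() if len(rel) else np.nan,
            "rel_var_mean": rel.mean() if len(rel) else np.nan,
            "rel_var_median": rel.median() if len(rel) else np.nan,
            "flags": ";".join(res.flags),
        })
        pairs = union.setdefault(res.trait_name, set())
        if not sig.empty:
            pairs.update(map(tuple, sig[["snp_a", "snp_b"]].to_numpy()))
    summary = pd.DataFrame(rows)
    union_rows = [{"trait": t, "n_union_pairs": len(p),
                   "n_possible": max((r.n_possible for r in results
                                      if r.trait_name == t), default=0)}
                  for t, p in sorted(union.items())]
    return summary, pd.DataFrame(union_rows)


def _stratum_table(pheno: PhenotypeTable, subjects, modal, K: int,
                   thresholds) -> pd.DataFrame:
    """Descriptive per-stratum table: BP spread and hypertensive fraction.

    Hypertension labels (diastolic > thresholds[0] or systolic >
    thresholds[1], office 140/90 mmHg rule) are descriptive only; they
    never enter the partition.
    """
    dia_col, sys_col = pheno.indicators[0], pheno.indicators[
        1 if len(pheno.indicators) > 1 else 0]
    data = pheno.data.loc[subjects]
    rows = []
    for k in range(K):
        sel = data[modal == k]
        dia = sel[dia_col].to_numpy(dtype=float)
        sys_ = sel[sys_col].to_numpy(dtype=float)
        hyper = (dia > thresholds[0]) | (sys_ > thresholds[1])
        rows.append({
            "subpopulation": k, "n_subjects": len(sel),
            f"{dia_col}_mean": dia.mean() if len(sel) else np.nan,
            f"{dia_col}_sd": dia.std(ddof=1) if len(sel) > 1 else np.nan,
            f"{sys_col}_mean": sys_.mean() if len(sel) else np.nan,
            f"{sys_col}_sd": sys_.std(ddof=1) if len(sel) > 1 else np.nan,
            "hypertensive_fraction": hyper.mean() if len(sel) else np.nan,
        })
    return pd.DataFrame(rows)
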