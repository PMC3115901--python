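"""Synthetic genotype/phenotype generator with known ground truth.

The generator emulates the structure of a mid-size population cohort:
a few thousand subjects, a candidate-gene SNP panel (tens of SNPs in a
couple of dozen genes, optionally in LD blocks), two correlated
blood-pressure indicator traits whose distribution is a covariate-gated
mixture of class-specific Gaussians, and planted single- or two-locus
genetic effects expressed through the orthogonal contrast scores so that
every downstream estimate has an analytic expectation.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; fixing the seed fixes every output bit.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .epistasis import contrast_maps
from .panel import GenotypeMatrix, PhenotypeTable

_ONE_LOCUS = ("A", "D")
_TWO_LOCUS = ("AA", "AD", "DA", "DD")
VALID_COMPONENTS = _ONE_LOCUS + _TWO_LOCUS


# ---------------------------------------------------------------------------
# panel specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PanelSpec:
    """SNP panel definition for the simulator.

    ``table`` needs columns ``snp_id``, ``gene``, ``allele_freq`` and
    optionally ``chromosome`` and ``ld_block``; SNPs sharing an
    ``ld_block`` label are simulated from a common haplotype chain whose
    adjacent-pair squared correlation is ``ld_r2[block]``.
    """

    table: pd.DataFrame
    ld_r2: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"snp_id", "gene", "allele_freq"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"panel spec missing columns: {sorted(missing)}")
        if t["snp_id"].duplicated().any():
            raise ValueError("panel snp_ids must be unique")
        p = t["allele_freq"].to_numpy(dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("allele frequencies must lie in (0, 1]")
        if "chromosome" not in t.columns:
            t["chromosome"] = "1"
        if "ld_block" not in t.columns:
            t["ld_block"] = None
        blocks = {b for b in t["ld_block"] if b is not None and b == b}
        undefined = blocks - set(self.ld_r2)
        if undefined:
            raise ValueError(f"ld_block without a target r2: {sorted(undefined)}")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def freq(self, snp_id: str) -> float:
        row = self.table[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return float(row["allele_freq"].iloc[0])

    def annotation(self) -> pd.DataFrame:
        """Panel annotation frame in GenotypeMatrix layout."""
        ann = self.table.set_index("snp_id")[["gene", "chromosome"]].copy()
        ann["counted_allele"] = "G"
        return ann


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _pair_haplotype_table(p_a: float, p_b: float, r2: float,
                          pair: tuple[str, str]) -> float:
    """Coupling-phase haplotype frequency f_AB achieving the target r2.

    D takes the positive root sqrt(r2 * pA qA pB qB); raises when the
    implied haplotype table leaves [0, 1].
    """
    q_a, q_b = 1 - p_a, 1 - p_b
    D = np.sqrt(r2 * p_a * q_a * p_b * q_b)
    f_ab = p_a * p_b + D
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if f_ab < lo - 1e-12 or f_ab > hi + 1e-12:
        raise ValueError(
            f"target r2={r2} infeasible for SNP pair {pair[0]}/{pair[1]} "
            f"with allele frequencies {p_a}/{p_b}")
    return float(min(max(f_ab, lo), hi))


def simulate_genotypes(spec: PanelSpec, n: int,
                       seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Draw an n-subject genotype matrix under HWE with optional LD blocks.

    SNPs outside LD blocks are drawn independently with genotype
    probabilities (q^2, 2pq, p^2).  SNPs inside a block are drawn as two
    independent haplotypes from a Markov chain over the block's SNPs
    whose adjacent pairs realize the block's target r2 (more distant
    pairs decay geometrically).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = spec.table
    dos = np.empty((n, len(t)), dtype=np.int8)

    in_block = t["ld_block"].notna() if t["ld_block"].dtype != object else \
        t["ld_block"].map(lambda b: b is not None and b == b)
    # independent SNPs
    for j in np.flatnonzero(~in_block.to_numpy()):
        p = float(t.loc[j, "allele_freq"])
        dos[:, j] = rng.binomial(1, p, n) + rng.binomial(1, p, n)
    # LD blocks: haplotype chains
    for block, idx in t[in_block].groupby("ld_block").groups.items():
        cols = list(idx)
        r2 = spec.ld_r2[block]
        freqs = [float(t.loc[j, "allele_freq"]) for j in cols]
        ids = [t.loc[j, "snp_id"] for j in cols]
        haps = np.empty((n, 2, len(cols)), dtype=np.int8)
        for h in range(2):
            haps[:, h, 0] = rng.random(n) < freqs[0]
            for k in range(1, len(cols)):
                pa, pb = freqs[k - 1], freqs[k]
                f_ab = _pair_haplotype_table(pa, pb, r2, (ids[k - 1], ids[k]))
                p_given1 = f_ab / pa
                p_given0 = (pb - f_ab) / (1 - pa)
                prev = haps[:, h, k - 1]
                pr = np.where(prev == 1, p_given1, p_given0)
                haps[:, h, k] = rng.random(n) < pr
        for slot, j in enumerate(cols):
            dos[:, j] = haps[:, 0, slot] + haps[:, 1, slot]

    subjects = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(subjects, spec.annotation(), dos)


# ---------------------------------------------------------------------------
# planted effects and population scenarios
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlantedEffect:
    """A genetic effect injected into the indicator traits.

    ``component`` is one of A, D (single locus) or AA, AD, DA, DD (two
    locus); ``beta`` is in trait units per contrast unit.  The effect is
    restricted to subjects of ``target_class`` ("all" applies it
    population-wide) and, when ``indicator`` is None, added to every
    indicator.
    """

    snp_a: str
    component: str
    beta: float
    snp_b: str | None = None
    target_class: int | str = "all"
    indicator: str | None = None

    def __post_init__(self) -> None:
        if self.component not in VALID_COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.component in _TWO_LOCUS and self.snp_b is None:
            raise ValueError(f"component {self.component} needs snp_b")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


def expected_components(effect: PlantedEffect, spec: PanelSpec) -> float:
    """Analytic variance contributed by a planted effect (trait units^2).

    Under HWE and inter-locus independence Var(w_A) = 2pq and
    Var(w_D) = (pq)^2, and the contrast product of independent zero-mean
    scores has variance equal to the product of the variances.
    """
    p_a = spec.freq(effect.snp_a)
    var = {"A": 2 * p_a * (1 - p_a), "D": (p_a * (1 - p_a)) ** 2}
    if effect.component in _ONE_LOCUS:
        v = var[effect.component]
    else:
        p_b = spec.freq(effect.snp_b)
        var_b = {"A": 2 * p_b * (1 - p_b), "D": (p_b * (1 - p_b)) ** 2}
        v = var[effect.component[0]] * var_b[effect.component[1]]
    return float(effect.beta ** 2 * v)


@dataclasses.dataclass
class Scenario:
    """Full description of one synthetic cohort.

    ``gating`` has shape (K, n_covariates + 1) on the log-odds scale
    (intercept first); class-membership probabilities are the softmax of
    ``z1 @ gating.T`` per subject.  ``class_means``/``class_sds`` are
    (K, n_indicators) in trait units; ``noise_sd`` adds measurement
    noise in quadrature on top of the class residual SD.
    """

    panel: PanelSpec
    n_subjects: int
    class_means: np.ndarray
    class_sds: np.ndarray
    gating: np.ndarray
    indicator_names: list[str]
    covariate_names: list[str]
    planted_effects: list[PlantedEffect] = dataclasses.field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_means = np.atleast_2d(np.asarray(self.class_means, float))
        self.class_sds = np.atleast_2d(np.asarray(self.class_sds, float))
        self.gating = np.atleast_2d(np.asarray(self.gating, float))
        K, q = self.class_means.shape
        if self.class_sds.shape != (K, q):
            raise ValueError("class_sds shape must match class_means")
        if np.any(self.class_sds <= 0):
            raise ValueError("all class SDs must be positive")
        if len(self.indicator_names) != q:
            raise ValueError("indicator_names do not match class_means")
        if self.gating.shape != (K, len(self.covariate_names) + 1):
            raise ValueError("gating must be (K, n_covariates + 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        panel_ids = set(self.panel.snp_ids)
        for e in self.planted_effects:
            for s in (e.snp_a, e.snp_b):
                if s is not None and s not in panel_ids:
                    raise ValueError(f"planted SNP {s!r} not in panel")
            if e.indicator is not None and e.indicator not in self.indicator_names:
                raise ValueError(f"planted indicator {e.indicator!r} unknown")

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]


@dataclasses.dataclass
class TruthRecord:
    """Ground truth accompanying a simulated cohort."""

    labels: np.ndarray               # true class per subject
    class_probs: np.ndarray          # gating probabilities (n, K)
    genetic_contribution: np.ndarray  # (n, q) planted trait contribution
    expected_variance: dict          # per planted effect: analytic variance
    scenario: Scenario

    def expected_relative_variance(self, effect_index: int,
                                   class_index: int,
                                   indicator: int = 0) -> float:
        """Analytic relative variance of one effect inside one class.

        Relative to the class's total phenotypic variance (effect
        variance + residual class variance + measurement noise).
        """
        sc = self.scenario
        eff = sc.planted_effects[effect_index]
        v_eff = expected_components(eff, sc.panel)
        v_resid = sc.class_sds[class_index, indicator] ** 2 + sc.noise_sd ** 2
        v_other = 0.0
        for i, other in enumerate(sc.planted_effects):
            if i == effect_index:
                continue
            applies = other.target_class in ("all", class_index)
            ind_ok = other.indicator is None or \
                other.indicator == sc.indicator_names[indicator]
            if applies and ind_ok:
                v_other += expected_components(other, sc.panel)
        return v_eff / (v_eff + v_other + v_resid)


def _softmax_rows(L: np.ndarray) -> np.ndarray:
    L = L - L.max(axis=1, keepdims=True)
    E = np.exp(L)
    return E / E.sum(axis=1, keepdims=True)


def simulate_population(scenario: Scenario
                        ) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Simulate a cohort: genotypes, phenotypes and the ground truth.

    Covariates are independent standard Gaussians; class labels come
    from the multinomial-logit gating; indicators are class-specific
    Gaussians plus the planted genetic contributions (orthogonal
    contrast scores coded with the panel's true allele frequencies).
    """
    rng = np.random.default_rng(scenario.seed)
    n, K = scenario.n_subjects, scenario.n_classes
    q = len(scenario.indicator_names)
    p_cov = len(scenario.covariate_names)

    G = simulate_genotypes(scenario.panel, n, rng)
    Z = rng.standard_normal((n, p_cov))
    Z1 = np.column_stack([np.ones(n), Z])
    probs = _softmax_rows(Z1 @ scenario.gating.T)
    u = rng.random(n)
    labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    genetic = np.zeros((n, q))
    for eff in scenario.planted_effects:
        wa_a, wd_a = contrast_maps(scenario.panel.freq(eff.snp_a))
        g_a = G.column(eff.snp_a)
        score_a = {"A": wa_a, "D": wd_a}
        if eff.component in _ONE_LOCUS:
            contrib = eff.beta * score_a[eff.component][g_a]
        else:
            wa_b, wd_b = contrast_maps(scenario.panel.freq(eff.snp_b))
            g_b = G.column(eff.snp_b)
            score_b = {"A": wa_b, "D": wd_b}
            contrib = eff.beta * (score_a[eff.component[0]][g_a]
                                  * score_b[eff.component[1]][g_b])
        if eff.target_class != "all":
            contrib = np.where(labels == int(eff.target_class), contrib, 0.0)
        if eff.indicator is None:
            genetic += contrib[:, None]
        else:
            genetic[:, scenario.indicator_names.index(eff.indicator)] += contrib

    eps = rng.standard_normal((n, q))
    sds = np.sqrt(scenario.class_sds[labels] ** 2 + scenario.noise_sd ** 2)
    Y = scenario.class_means[labels] + genetic + eps * sds

    data = pd.DataFrame(
        np.column_stack([Y, Z]),
        index=pd.Index(G.subjects, name="subject_id"),
        columns=[*scenario.indicator_names, *scenario.covariate_names])
    pheno = PhenotypeTable(data, list(scenario.indicator_names),
                           list(scenario.covariate_names))
    expected = {i: expected_components(e, scenario.panel)
                for i, e in enumerate(scenario.planted_effects)}
    truth = TruthRecord(labels, probs, genetic, expected, scenario)
    return G, pheno, truth


# ---------------------------------------------------------------------------
# reference scenario
# ---------------------------------------------------------------------------

_GENES = ["SPTLC1", "SPTLC3", "CERS1", "CERS2", "CERS4", "CERS6", "DEGS1",
          "ASAH1", "ACER1", "ACER2", "ACER3", "SPHK1", "SPHK2", "SPHKAP",
          "SGPL1", "SGPP1", "SGPP2", "SMPD1", "UGCG", "GCLC", "GCLM",
          "ELOVL3", "FFAR1"]

_FREQ_CYCLE = [0.50, 0.35, 0.20, 0.45, 0.30, 0.25, 0.40, 0.15, 0.10, 0.05]


def monica_like_panel() -> PanelSpec:
    """Synthetic 45-SNP / 23-gene sphingolipid-pathway panel.

    The gene symbols are the ceramide/sphingosine-1-phosphate rheostat
    enzymes; SNP identifiers and allele frequencies are synthetic stand-ins
    (the study panel itself is not public).  Two intragenic LD blocks are
    included so stratum QC sees realistic intragenic correlation.
    """
    rows = []
    k = 0
    for gi, gene in enumerate(_GENES):
        n_snps = 2 if gi < 22 else 1   # 22*2 + 1 = 45
        for s in range(n_snps):
            rows.append({"snp_id": f"{gene}_{s + 1}", "gene": gene,
                         "chromosome": str(gi + 1),
                         "allele_freq": _FREQ_CYCLE[k % len(_FREQ_CYCLE)],
                         "ld_block": None})
            k += 1
    t = pd.DataFrame(rows)
    # intragenic LD blocks in two genes with matched frequencies
    for gene, block in (("CERS2", "blk_CERS2"), ("SMPD1", "blk_SMPD1")):
        sel = t["gene"] == gene
        t.loc[sel, "allele_freq"] = 0.3
        t.loc[sel, "ld_block"] = block
    return PanelSpec(t, ld_r2={"blk_CERS2": 0.8, "blk_SMPD1": 0.8})


def monica_like(K_true: int = 4, n_subjects: int = 2523, seed: int = 0,
                planted_relative: float = 0.5) -> Scenario:
    """Reference scenario mirroring the cohort scale of the study design.

    n=2,523 subjects, 45 SNPs in 23 genes, two indicator traits
    (diastolic/systolic, mmHg), 10 standard-normal covariates, K_true
    latent classes (2-14) with a hypertensive top class, and a planted
    additive-additive interaction between SPTLC3 and CERS4 SNPs in the
    top class sized to the requested relative variance (default 0.5, the
    scale of the largest relative epistatic variance the method is meant
    to detect).
    """
    if not 2 <= K_true <= 14:
        raise ValueError("K_true must be between 2 and 14")
    panel = monica_like_panel()
    # planted loci at intermediate frequency: the large-relative-variance
    # regime the scan is meant to detect lives at common alleles
    t = panel.table
    t.loc[t["snp_id"].isin(["SPTLC3_1", "CERS4_1"]), "allele_freq"] = 0.5
    # class means walk from normotensive to hypertensive
    dia = np.linspace(68.0, 112.0, K_true)
    sys_ = np.linspace(108.0, 182.0, K_true)
    means = np.column_stack([dia, sys_])
    sds = np.tile([4.0, 6.0], (K_true, 1))
    covariates = ["homares", "bnp", "compliance", "supar", "vldl", "crp",
                  "age", "bmi", "apoa1", "whr"]
    gating = np.zeros((K_true, 11))
    # shrinking intercepts give a small top (hypertensive) class; the
    # first three covariates shift membership toward higher classes
    gating[:, 0] = np.linspace(1.2, 0.0, K_true)
    for k in range(K_true):
        gating[k, 1] = 0.8 * k / max(K_true - 1, 1)
        gating[k, 2] = 0.5 * k / max(K_true - 1, 1)
        gating[k, 3] = -0.5 * k / max(K_true - 1, 1)
    top = K_true - 1
    # size the planted AA effect: relative = V / (V + sd^2) on diastolic
    v_resid = sds[top, 0] ** 2
    v_target = planted_relative / (1 - planted_relative) * v_resid
    p = panel.freq("SPTLC3_1")
    var_w = 2 * p * (1 - p)
    p2 = panel.freq("CERS4_1")
    var_w2 = 2 * p2 * (1 - p2)
    beta = np.sqrt(v_target / (var_w * var_w2))
    effects = [PlantedEffect("SPTLC3_1", "AA", float(beta), "CERS4_1",
                             target_class=top, indicator="diastolic"),
               PlantedEffect("GCLM_1", "A", 0.8, target_class="all")]
    return Scenario(panel, n_subjects, means, sds, gating,
                    ["diastolic", "systolic"], covariates, effects,
                    noise_sd=0.0, seed=seed)
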