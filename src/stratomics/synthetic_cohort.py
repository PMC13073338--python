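"""Synthetic stratified case-control cohorts with planted ground truth.

The generator emulates the statistical structure a genotype-stratified
plasma proteomics/metabolomics study assumes: several genotype strata of
case/control samples, cases ~5 years older than controls, two collection
batches with an additive log10 shift, log-normal analyte abundances, and
per-analyte disease effects that are shared across strata, specific to one
stratum, or opposite-signed between two designated strata.  Every planted
quantity is returned as ground truth so each downstream stage can be tested
against construction.

Effect-size convention
----------------------
``effect_size_logodds`` is the log-odds of case status per standard
deviation of the (batch-corrected, log10) analyte.  Abundances are drawn
class-conditionally, ``log10 x | status ~ N(baseline + batch_shift*batch +
delta*status, noise_sd^2)``, and the case shift ``delta`` is calibrated so
that the logistic-regression coefficient on the standardized analyte equals
the requested log-odds asymptotically: with Gaussian class conditionals the
induced slope per unit is ``delta/noise_sd^2``, and solving
``(delta/noise_sd^2) * sqrt(noise_sd^2 + delta^2 p(1-p)) = beta`` for
``delta`` accounts for the effect's own contribution to the marginal SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, ConfigError, GeneSetCollection, StateError

logger = logging.getLogger(__name__)

# 13 major human cell types, blood-centric reference panel.
DEFAULT_CELL_TYPES = (
    "Stem Cell", "Mast Cell", "Hematopoietic Precursor Cell", "Lymphocyte",
    "Mononuclear Cell", "T Cell", "B Cell", "NK Cell", "Monocyte",
    "Glial Cell", "Erythrocyte", "Hepatocyte", "Myeloid Leukocyte",
)

SUPER_PATHWAYS = (
    "Lipid", "Amino Acid", "Nucleotide", "Carbohydrate",
    "Xenobiotics", "Peptide", "Energy", "Cofactors and Vitamins",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a mid-sized stratified study: four genotype strata of
    600 samples at 45% case prevalence (cases on average five years older),
    two equal collection batches offset by 0.3 log10 units, analyte noise of
    0.25 log10 units, and planted per-SD log-odds effects of 0.8.
    """

    n_samples_per_stratum: int = 600
    case_fraction: float = 0.45
    strata: tuple[str, ...] = ("33", "34", "44", "2x")
    n_analytes: int = 300
    frac_shared_effects: float = 0.10
    frac_stratum_specific: float = 0.05
    frac_opposite: float = 0.05
    effect_size_logodds: float = 0.8
    age_mean_case: float = 75.0
    age_mean_control: float = 70.0
    age_sd: float = 8.0
    batch_shift: float = 0.3
    noise_sd: float = 0.25
    missing_rate: float = 0.0
    n_cell_types: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_stratum <= 0:
            raise ConfigError("n_samples_per_stratum must be positive")
        if self.n_analytes <= 0:
            raise ConfigError("n_analytes must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigError("case_fraction must be in (0, 1)")
        for name in ("frac_shared_effects", "frac_stratum_specific",
                     "frac_opposite", "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        total = (self.frac_shared_effects + self.frac_stratum_specific
                 + self.frac_opposite)
        if total > 1.0 + 1e-12:
            raise ConfigError("effect fractions must sum to <= 1")
        if self.effect_size_logodds < 0:
            raise ConfigError("effect_size_logodds must be nonnegative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if len(self.strata) < 1:
            raise ConfigError("at least one stratum required")
        if self.frac_opposite > 0 and len(self.strata) < 2:
            raise ConfigError("opposite effects need >= 2 strata")
        if self.n_cell_types < 2:
            raise ConfigError("n_cell_types must be >= 2")


@dataclass
class GroundTruth:
    """Planted truth for one generated cohort.

    ``coef`` holds the planted per-SD log-odds coefficient for every analyte
    (rows) in every stratum (columns); ``effect_class`` is one of ``null``,
    ``shared``, ``stratum_specific``, ``opposite``.
    """

    effect_class: pd.Series
    coef: pd.DataFrame
    case_shift: pd.DataFrame  # delta on the log10 scale, per stratum
    analyte_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=str))

    def analytes_of_class(self, name: str) -> pd.Index:
        return self.effect_class.index[self.effect_class == name]


@dataclass
class QCTruth:
    """Planted QC violations: criterion number -> ids (aptamers for 1-4 and
    6, samples for 5)."""

    flags: dict[int, frozenset[str]]

    def all_aptamers(self) -> frozenset[str]:
        out: set[str] = set()
        for crit in (1, 2, 3, 4, 6):
            out |= self.flags.get(crit, frozenset())
        return frozenset(out)


@dataclass
class QCAuxTables:
    """Vendor-style auxiliary tables consumed by the QC chain."""

    buffer_stats: pd.DataFrame       # index aptamer; columns buffer_mean, buffer_sd
    calibration: pd.DataFrame        # index aptamer; one column per plate
    cv: pd.Series                    # index aptamer; median replicate CV


@dataclass
class QCFixture:
    matrix: AnalyteMatrix
    aux: QCAuxTables
    truth: QCTruth


def _calibrated_shift(beta_per_sd: float, noise_sd: float, pq: float) -> float:
    """Case/control mean shift delta yielding an asymptotic per-SD logistic
    log-odds of ``beta_per_sd`` (see module docstring)."""
    if beta_per_sd == 0.0:
        return 0.0
    sign = math.copysign(1.0, beta_per_sd)
    beta = abs(beta_per_sd)
    var = noise_sd ** 2
    u = var * (math.sqrt(1.0 + 4.0 * pq * beta * beta) - 1.0) / (2.0 * pq)
    return sign * math.sqrt(u)


class SyntheticStudy:
    """Stateful generator: cohort first, then annotations keyed to it."""

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self._cohort: tuple[AnalyteMatrix, pd.DataFrame, GroundTruth] | None = None

    # ------------------------------------------------------------------
    def generate_cohort(self) -> tuple[AnalyteMatrix, pd.DataFrame, GroundTruth]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        strata = list(cfg.strata)
        n = cfg.n_samples_per_stratum
        n_cases = int(round(cfg.case_fraction * n))
        if n_cases == 0 or n_cases == n:
            raise ConfigError("case_fraction leaves a stratum without one class")

        # --- samples ---------------------------------------------------
        rows = []
        counter = 0
        for stratum in strata:
            status = np.array(["AD"] * n_cases + ["CO"] * (n - n_cases))
            age = np.where(
                status == "AD",
                rng.normal(cfg.age_mean_case, cfg.age_sd, size=n),
                rng.normal(cfg.age_mean_control, cfg.age_sd, size=n),
            ).round(1)
            sex = np.array(["M", "F"] * (n // 2) + ["M"] * (n % 2))
            rng.shuffle(sex)
            batch = np.array(["b1"] * (n // 2) + ["b2"] * (n - n // 2))
            rng.shuffle(batch)
            for k in range(n):
                counter += 1
                rows.append((f"S{counter:06d}", status[k], age[k], sex[k],
                             stratum, batch[k], "d1" if batch[k] == "b1" else "d2"))
        meta = pd.DataFrame(rows, columns=["sample_id", "status", "age", "sex",
                                           "stratum", "batch", "dataset"])
        meta = meta.set_index("sample_id", drop=False)

        # --- analyte effect classes ------------------------------------
        m = cfg.n_analytes
        analytes = pd.Index([f"APT{i + 1:05d}" for i in range(m)], name="analyte_id")
        n_shared = int(round(cfg.frac_shared_effects * m))
        n_specific = int(round(cfg.frac_stratum_specific * m))
        n_opposite = int(round(cfg.frac_opposite * m))
        order = rng.permutation(m)
        classes = pd.Series("null", index=analytes, name="effect_class")
        shared_idx = analytes[order[:n_shared]]
        specific_idx = analytes[order[n_shared:n_shared + n_specific]]
        opposite_idx = analytes[order[n_shared + n_specific:
                                      n_shared + n_specific + n_opposite]]
        classes.loc[shared_idx] = "shared"
        classes.loc[specific_idx] = "stratum_specific"
        classes.loc[opposite_idx] = "opposite"

        coef = pd.DataFrame(0.0, index=analytes, columns=strata)
        beta = cfg.effect_size_logodds
        signs = rng.choice([-1.0, 1.0], size=m)
        for j, a in enumerate(analytes):
            if classes[a] == "shared":
                coef.loc[a, :] = signs[j] * beta
            elif classes[a] == "stratum_specific":
                stratum = strata[int(rng.integers(len(strata)))]
                coef.loc[a, stratum] = signs[j] * beta
            elif classes[a] == "opposite":
                # opposite-signed between the two designated (first two) strata
                coef.loc[a, strata[0]] = signs[j] * beta
                coef.loc[a, strata[1]] = -signs[j] * beta

        pq = (n_cases / n) * (1.0 - n_cases / n)
        shift = coef.map(lambda b: _calibrated_shift(b, cfg.noise_sd, pq))

        # --- abundances -------------------------------------------------
        baseline = rng.uniform(2.5, 4.5, size=m)
        is_case = (meta["status"] == "AD").to_numpy(dtype=float)
        is_b2 = (meta["batch"] == "b2").to_numpy(dtype=float)
        stratum_codes = meta["stratum"].to_numpy()
        log10x = np.empty((m, len(meta)))
        shift_arr = shift.to_numpy()
        stratum_col = {s: i for i, s in enumerate(strata)}
        col_of_sample = np.array([stratum_col[s] for s in stratum_codes])
        delta_per_sample = shift_arr[:, col_of_sample] * is_case[None, :]
        log10x = (baseline[:, None]
                  + cfg.batch_shift * is_b2[None, :]
                  + delta_per_sample
                  + rng.normal(0.0, cfg.noise_sd, size=(m, len(meta))))
        values = np.power(10.0, log10x)
        if cfg.missing_rate > 0:
            mask = rng.random(size=values.shape) < cfg.missing_rate
            values[mask] = np.nan
        data = pd.DataFrame(values, index=analytes, columns=meta.index.copy())
        matrix = AnalyteMatrix(data, dataset="synthetic", scale="raw")

        gene_map = _analyte_gene_map(analytes)
        truth = GroundTruth(effect_class=classes, coef=coef, case_shift=shift,
                            analyte_gene=gene_map)
        self._cohort = (matrix, meta, truth)
        return matrix, meta, truth

    # ------------------------------------------------------------------
    def generate_annotations(self) -> tuple[GeneSetCollection, pd.DataFrame,
                                            nx.Graph, pd.DataFrame]:
        """Gene sets, cell-type reference, PPI background and analyte
        annotation matched to the generated cohort.

        Must be called after :meth:`generate_cohort` (the annotation universe
        is the cohort's analyte/gene ids).
        """
        if self._cohort is None:
            raise StateError("generate_annotations called before generate_cohort")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        _, _, truth = self._cohort
        gene_map = truth.analyte_gene
        genes = sorted(set(gene_map))
        connectors = [f"CONN{i + 1:04d}" for i in range(max(20, len(genes) // 5))]
        universe = genes + connectors

        # --- gene sets: sizes spanning [5, 600] + one planted enriched set
        sizes = [5, 8, 10, 25, 50, 100, 200, 350, 500, 600]
        sets: list[tuple[str, str, frozenset[str]]] = []
        for i, size in enumerate(sizes):
            size = min(size, len(universe))
            members = rng.choice(universe, size=size, replace=False)
            sets.append((f"RANDSET{i + 1:02d}", f"random set of {size}",
                         frozenset(members)))
        shared_genes = sorted(set(gene_map[truth.analytes_of_class("shared")]))
        n_take = max(1, int(round(0.8 * len(shared_genes))))
        take = sorted(rng.choice(shared_genes, size=n_take, replace=False)) \
            if shared_genes else []
        fillers = rng.choice([g for g in universe if g not in take],
                             size=max(0, 12 - len(take)), replace=False)
        planted = frozenset(list(take) + list(fillers))
        if planted:
            sets.append(("PLANTED_SHARED_SET",
                         "contains 80% of shared-effect genes", planted))
        collection = GeneSetCollection(sets)

        # --- cell-type reference ---------------------------------------
        cell_types = list(DEFAULT_CELL_TYPES[:cfg.n_cell_types])
        while len(cell_types) < cfg.n_cell_types:
            cell_types.append(f"Cell Type {len(cell_types) + 1}")
        base = rng.gamma(2.0, 1.0, size=(len(genes), len(cell_types)))
        specific = rng.random(len(genes)) < 0.6
        dominant = rng.integers(len(cell_types), size=len(genes))
        for g in np.nonzero(specific)[0]:
            base[g, dominant[g]] = base[g].max() * rng.uniform(2.0, 4.0)
        reference = pd.DataFrame(base, index=genes, columns=cell_types)

        # --- PPI background: random tree over the universe + extra edges
        nodes = list(universe)
        rng.shuffle(nodes)
        graph = nx.Graph()
        graph.add_node(nodes[0])
        for i in range(1, len(nodes)):
            parent = nodes[int(rng.integers(i))]
            graph.add_edge(nodes[i], parent)
        n_extra = 2 * len(nodes)
        for _ in range(n_extra):
            a, b = rng.choice(len(nodes), size=2, replace=False)
            graph.add_edge(nodes[a], nodes[b])

        # --- analyte annotation ----------------------------------------
        supers = rng.choice(len(SUPER_PATHWAYS), size=len(gene_map))
        ann = pd.DataFrame({
            "analyte_id": gene_map.index,
            "gene": gene_map.to_numpy(),
            "super_pathway": [SUPER_PATHWAYS[s] for s in supers],
            "sub_pathway": [f"{SUPER_PATHWAYS[s]} subclass "
                            f"{int(rng.integers(1, 4))}" for s in supers],
        }).set_index("analyte_id", drop=False)
        return collection, reference, graph, ann


def _analyte_gene_map(analytes: pd.Index) -> pd.Series:
    """Mostly 1:1 analyte->gene map; every 20th analyte shares its gene with
    the previous one (multiple aptamers per gene, as on real panels)."""
    genes = []
    gene_no = 0
    for i in range(len(analytes)):
        if i % 20 == 19 and i > 0:
            genes.append(f"GENE{gene_no:05d}")
        else:
            gene_no += 1
            genes.append(f"GENE{gene_no:05d}")
    return pd.Series(genes, index=analytes, name="gene")


def generate_cohort(config: SyntheticConfig):
    """Convenience wrapper: one-shot cohort generation."""
    return SyntheticStudy(config).generate_cohort()


def generate_annotations(config: SyntheticConfig):
    """Convenience wrapper: cohort + annotations in one call."""
    study = SyntheticStudy(config)
    cohort = study.generate_cohort()
    return cohort, study.generate_annotations()


# ----------------------------------------------------------------------
# QC fixture
# ----------------------------------------------------------------------

def generate_qc_fixture(config: SyntheticConfig) -> QCFixture:
    """Matrix plus auxiliary tables planting >=3 violators of each QC
    criterion, with the planted flags as ground truth.

    Construction guarantees each violator trips exactly one criterion (the
    one it is planted for), so running the QC chain on the fixture must
    recover ``truth.flags`` exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_samples = 60
    n_aptamers = 30
    samples = [f"Q{i + 1:03d}" for i in range(n_samples)]
    aptamers = [f"FIXAPT{i + 1:03d}" for i in range(n_aptamers)]

    crit1 = aptamers[0:3]     # low signal vs dilution buffer
    crit2 = aptamers[3:6]     # plate calibration-factor deviation
    crit3 = aptamers[6:9]     # high median replicate CV
    crit4 = aptamers[9:12]    # >15% of samples outside 1.5xIQR fences
    crit6 = aptamers[12:15]   # fence violations shared by the sample outliers
    clean = aptamers[15:]     # 15 clean aptamers
    outlier_samples = samples[:5]
    normal_samples = samples[5:]

    baseline = rng.uniform(3.0, 4.0, size=n_aptamers)
    log10x = baseline[:, None] + rng.normal(0.0, 0.1, size=(n_aptamers, n_samples))
    log10x = pd.DataFrame(log10x, index=aptamers, columns=samples)

    # criterion 4: 10/60 samples (16.7%) pushed +/-1.5 log10 units out,
    # rotating through normal samples so no sample collects >1 extreme value
    slot = 0
    for apt in crit4:
        for k in range(10):
            s = normal_samples[slot % len(normal_samples)]
            slot += 1
            log10x.loc[apt, s] += 1.5 if k % 2 == 0 else -1.5

    # criterion 6 aptamers: +2 in every planted sample outlier (5/5 = 100%
    # >= 80% shared), but only 5/60 = 8.3% of samples -> below criterion 4
    for apt in crit6:
        log10x.loc[apt, outlier_samples] += 2.0

    # criterion 5 samples: each outlier sample gets 6 helper aptamers (from
    # the clean pool, each helper used in exactly 2 outlier samples -> 40%
    # < 80% so helpers never trip criterion 6) plus the 3 criterion-6
    # aptamers: 9/30 = 30% > 15% of its values outside fences
    helper_iter = 0
    for s in outlier_samples:
        for _ in range(6):
            apt = clean[helper_iter % len(clean)]
            helper_iter += 1
            log10x.loc[apt, s] += 2.0

    values = np.power(10.0, log10x)
    matrix = AnalyteMatrix(values, dataset="qc_fixture", scale="raw")

    # --- auxiliary tables ---------------------------------------------
    buffer_mean = pd.Series(10.0, index=aptamers)
    buffer_sd = pd.Series(5.0, index=aptamers)
    for apt in crit1:
        # put the buffer threshold at this aptamer's 20th percentile so 20%
        # of samples (>15%) sit below buffer_mean + 2*buffer_sd
        q20 = float(np.quantile(values.loc[apt].to_numpy(), 0.20))
        buffer_sd[apt] = q20 * 0.05
        buffer_mean[apt] = q20 - 2.0 * buffer_sd[apt]
    buffer_stats = pd.DataFrame({"buffer_mean": buffer_mean,
                                 "buffer_sd": buffer_sd})

    plates = [f"P{i + 1}" for i in range(5)]
    calib = pd.DataFrame(rng.normal(1.0, 0.02, size=(n_aptamers, len(plates))),
                         index=aptamers, columns=plates)
    for apt in crit2:
        calib.loc[apt, plates[0]] = 1.65   # |1.65 - median(~1.0)| > 0.5

    cv = pd.Series(rng.uniform(0.03, 0.08, size=n_aptamers), index=aptamers)
    cv[crit3] = 0.30

    truth = QCTruth(flags={
        1: frozenset(crit1),
        2: frozenset(crit2),
        3: frozenset(crit3),
        4: frozenset(crit4),
        5: frozenset(outlier_samples),
        6: frozenset(crit6),
    })
    return QCFixture(matrix=matrix,
                     aux=QCAuxTables(buffer_stats=buffer_stats,
                                     calibration=calib, cv=cv),
                     truth=truth)
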