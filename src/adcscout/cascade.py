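"""Nine-stage tumor-selective target identification cascade.

Starting from a gene universe with membrane/protein-evidence/surfaceome
annotations, the cascade keeps genes that (1) encode predicted membrane
proteins, (2) have evidence at protein level, (3) are not stained high in any
critical normal tissue, (4) reach a quasi H-score above the selectivity
threshold in at least one tumor type, (5) belong to the in-silico surfaceome,
(6a) have normal-tissue mRNA categories aligned with IHC staining, (6b) clear
the quasi H threshold in both the IHC- and the tumor-mRNA-derived score,
(7) are not highly expressed on hematopoietic stem / multipotent progenitor
cells, and (8) meet at least one of five evidence criteria.

The quasi H-score summarizes a staining distribution on a 0-300 scale:

    score = 1 * %low + 2 * %medium + 3 * %high

over patients (IHC source) or samples binned by within-cohort quartiles
(mRNA source).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import CascadeTrace, ConfigError, ExpressionMatrix, Level

__all__ = [
    "CRITICAL_TISSUES",
    "DEFAULT_TUMOR_TYPES",
    "NORMAL_TISSUES",
    "FilterResult",
    "CascadeConfig",
    "CascadeResult",
    "quasi_h_from_fractions",
    "ihc_quasi_h_table",
    "categorize_quartiles",
    "quasi_h_from_expression",
    "mrna_quasi_h_table",
    "ihc_tissue_categories",
    "mrna_tissue_categories",
    "check_consistency_6a",
    "filter_membrane",
    "filter_protein_evidence",
    "filter_membrane_evidence",
    "filter_critical_normal",
    "filter_tumor_quasi_h",
    "filter_surfaceome",
    "filter_dual_quasi_h",
    "filter_hsc_mpp",
    "evidence_score",
    "filter_evidence",
    "run_cascade",
]

#: The 13 critical normal tissues whose high staining disqualifies a target.
CRITICAL_TISSUES = (
    "lung",
    "oral mucosa",
    "esophagus",
    "stomach",
    "duodenum",
    "small intestine",
    "colon",
    "rectum",
    "liver",
    "kidney",
    "heart muscle",
    "skin",
    "bone marrow",
)

#: 44 normal tissue types (critical 13 first) in the IHC atlas dialect.
NORMAL_TISSUES = CRITICAL_TISSUES + (
    "cerebral cortex",
    "cerebellum",
    "hippocampus",
    "caudate",
    "hypothalamus",
    "pituitary gland",
    "thyroid gland",
    "parathyroid gland",
    "adrenal gland",
    "nasopharynx",
    "bronchus",
    "salivary gland",
    "tonsil",
    "appendix",
    "gallbladder",
    "pancreas",
    "lymph node",
    "spleen",
    "testis",
    "epididymis",
    "seminal vesicle",
    "prostate",
    "breast",
    "endometrium",
    "cervix",
    "fallopian tube",
    "ovary",
    "placenta",
    "vagina",
    "urinary bladder",
    "smooth muscle",
    "skeletal muscle",
    "adipose tissue",
    "soft tissue",
    "retina",
)

#: 20 tumor-type codes used for the quasi H-score matrix by default.
DEFAULT_TUMOR_TYPES = (
    "BLCA", "BRCA", "CESC", "COAD", "GBM", "HNSC", "KIRC", "LGG", "LIHC",
    "LUAD", "LUSC", "OV", "PAAD", "PRAD", "READ", "SKCM", "STAD", "TGCT",
    "THCA", "UCEC",
)


class FilterResult(NamedTuple):
    kept: list[str]
    dropped: dict[str, str]


# ---------------------------------------------------------------------------
# quasi H-score
# ---------------------------------------------------------------------------


def quasi_h_from_fractions(frac_low: float, frac_medium: float, frac_high: float) -> float:
    """Quasi H-score from percentages of patients at each staining level.

    ``score = 1*frac_low + 2*frac_medium + 3*frac_high``, ranging 0 (all
    patients not detected) to 300 (all patients high).
    """
    for name, v in (("frac_low", frac_low), ("frac_medium", frac_medium), ("frac_high", frac_high)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    if frac_low + frac_medium + frac_high > 100.0 + 1e-9:
        raise ValueError("staining fractions sum to more than 100%")
    return 1.0 * frac_low + 2.0 * frac_medium + 3.0 * frac_high


def ihc_quasi_h_table(pathology: pd.DataFrame) -> pd.DataFrame:
    """Gene x cancer-type matrix of IHC-derived quasi H-scores (NaN = no data)."""
    if pathology.empty:
        return pd.DataFrame()
    scores = pathology.apply(
        lambda r: quasi_h_from_fractions(r["frac_low"], r["frac_medium"], r["frac_high"]),
        axis=1,
    )
    return (
        pathology.assign(score=scores)
        .pivot_table(index="gene", columns="cancer_type", values="score", aggfunc="mean")
        .rename_axis(index=None, columns=None)
    )


# ---------------------------------------------------------------------------
# quartile categorization
# ---------------------------------------------------------------------------


def categorize_quartiles(values, scheme: str = "four_level") -> np.ndarray:
    """Bin abundances into ordinal categories by their own Q1/Q3.

    Quartiles are computed over all supplied values (zeros included) with
    linear interpolation between order statistics.  ``four_level``: 0 maps to
    not detected, (0, Q1] low, (Q1, Q3] medium, above Q3 high.
    ``three_level``: below Q1 low, [Q1, Q3] medium, above Q3 high.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if v.size < 4:
        raise ValueError("insufficient samples for quartile categorization (need >= 4)")
    if np.isnan(v).any():
        raise ValueError("values must be finite")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    out = np.empty(v.size, dtype=np.int64)
    if scheme == "four_level":
        out[:] = Level.MEDIUM
        out[v == 0.0] = Level.NOT_DETECTED
        out[(v > 0.0) & (v <= q1)] = Level.LOW
        out[v > q3] = Level.HIGH
    elif scheme == "three_level":
        out[:] = Level.MEDIUM
        out[v < q1] = Level.LOW
        out[v > q3] = Level.HIGH
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out


def _score_from_levels(levels: np.ndarray) -> float:
    n = levels.size
    pct = lambda lvl: 100.0 * np.count_nonzero(levels == lvl) / n  # noqa: E731
    return pct(Level.LOW) + 2.0 * pct(Level.MEDIUM) + 3.0 * pct(Level.HIGH)


def quasi_h_from_expression(matrix: ExpressionMatrix, cohort: str, gene: str) -> float:
    """mRNA-derived quasi H-score for one gene within one tumor cohort.

    Cohort samples are binned by the gene's own within-cohort quartiles
    (three-level scheme) and scored 1/2/3 per the staining formula.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    samples = matrix.cohort_samples(cohort)
    if len(samples) < 4:
        raise ValueError(f"cohort {cohort!r} has fewer than 4 samples")
    values = matrix.values.loc[gene, samples].to_numpy(float)
    return _score_from_levels(categorize_quartiles(values, "three_level"))


def mrna_quasi_h_table(matrix: ExpressionMatrix, genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Gene x cohort matrix of mRNA-derived quasi H-scores."""
    genes = list(genes) if genes is not None else matrix.genes
    present = [g for g in genes if g in matrix.values.index]
    cohorts = [c for c in matrix.cohorts() if len(matrix.cohort_samples(c)) >= 4]
    out = pd.DataFrame(index=present, columns=cohorts, dtype=float)
    for cohort in cohorts:
        samples = matrix.cohort_samples(cohort)
        block = matrix.values.loc[present, samples].to_numpy(float)
        for i, gene in enumerate(present):
            out.loc[gene, cohort] = _score_from_levels(
                categorize_quartiles(block[i], "three_level")
            )
    return out


# ---------------------------------------------------------------------------
# per-tissue category maps (stage 6a)
# ---------------------------------------------------------------------------


def ihc_tissue_categories(normal: pd.DataFrame) -> pd.DataFrame:
    """Gene x tissue IHC category (ordinal int; max over cell types; NaN = no data)."""
    if normal.empty:
        return pd.DataFrame()
    codes = normal["level"].cat.codes.astype(float)
    return (
        normal.assign(_code=codes)
        .pivot_table(index="gene", columns="tissue", values="_code", aggfunc="max")
        .rename_axis(index=None, columns=None)
    )


def mrna_tissue_categories(normal_mrna: ExpressionMatrix) -> pd.DataFrame:
    """Gene x tissue mRNA category from per-gene four-level quartile binning."""
    rows = {}
    for gene in normal_mrna.genes:
        values = normal_mrna.values.loc[gene].to_numpy(float)
        rows[gene] = categorize_quartiles(values, "four_level").astype(float)
    return pd.DataFrame.from_dict(rows, orient="index", columns=normal_mrna.samples)


def check_consistency_6a(
    mrna_categories: pd.DataFrame,
    ihc_categories: pd.DataFrame,
    genes: Iterable[str],
    policy: str = "within_one",
) -> FilterResult:
    """Per-gene consistency of normal-tissue mRNA vs IHC categories.

    Under ``within_one`` (default) a gene passes iff every tissue present in
    both maps differs by at most one ordinal level; ``exact`` requires equal
    categories.  Tissues present in only one map are ignored; a gene with no
    overlapping tissue fails.
    """
    if policy not in ("within_one", "exact"):
        raise ConfigError(f"unknown consistency policy {policy!r}")
    tol = 1 if policy == "within_one" else 0
    kept, dropped = [], {}
    for gene in genes:
        if gene not in mrna_categories.index or gene not in ihc_categories.index:
            dropped[gene] = "no overlapping evidence"
            continue
        m = mrna_categories.loc[gene].dropna()
        h = ihc_categories.loc[gene].dropna()
        shared = m.index.intersection(h.index)
        if len(shared) == 0:
            dropped[gene] = "no overlapping evidence"
            continue
        dist = (m[shared] - h[shared]).abs()
        worst = dist.idxmax()
        if dist[worst] > tol:
            dropped[gene] = (
                f"mRNA/IHC category distance {int(dist[worst])} in tissue {worst!r}"
            )
        else:
            kept.append(gene)
    return FilterResult(kept, dropped)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _ann_lookup(annotations: pd.DataFrame, column: str) -> pd.Series:
    return annotations.set_index("gene")[column]


def filter_membrane(annotations: pd.DataFrame, genes: Iterable[str]) -> FilterResult:
    flag = _ann_lookup(annotations, "is_membrane")
    kept, dropped = [], {}
    for g in genes:
        if bool(flag.get(g, False)):
            kept.append(g)
        else:
            dropped[g] = "no membrane annotation"
    return FilterResult(kept, dropped)


def filter_protein_evidence(annotations: pd.DataFrame, genes: Iterable[str]) -> FilterResult:
    flag = _ann_lookup(annotations, "has_protein_evidence")
    kept, dropped = [], {}
    for g in genes:
        if bool(flag.get(g, False)):
            kept.append(g)
        else:
            dropped[g] = "no protein evidence"
    return FilterResult(kept, dropped)


def filter_membrane_evidence(annotations: pd.DataFrame, genes: Iterable[str] | None = None) -> FilterResult:
    """Membrane annotation AND protein-level evidence (stages 1-2 combined)."""
    genes = list(genes) if genes is not None else list(annotations["gene"])
    first = filter_membrane(annotations, genes)
    second = filter_protein_evidence(annotations, first.kept)
    return FilterResult(second.kept, {**first.dropped, **second.dropped})


def filter_critical_normal(
    normal: pd.DataFrame,
    genes: Iterable[str],
    critical_tissues: Iterable[str] = CRITICAL_TISSUES,
) -> FilterResult:
    """Drop genes stained high in any critical tissue (any cell type).

    Genes with no records in critical tissues are kept.
    """
    critical = list(critical_tissues)
    if not critical:
        raise ConfigError("critical tissue list must be non-empty")
    known = set(normal["tissue"]) if not normal.empty else set()
    unknown = [t for t in critical if t not in known]
    if unknown:
        raise ConfigError(f"critical tissues absent from normal-tissue table: {unknown}")
    high = normal[
        normal["tissue"].isin(critical) & (normal["level"] == Level.HIGH.label)
    ]
    first_high = high.groupby("gene")["tissue"].first()
    kept, dropped = [], {}
    for g in genes:
        if g in first_high.index:
            dropped[g] = f"high expression in critical tissue {first_high[g]!r}"
        else:
            kept.append(g)
    return FilterResult(kept, dropped)


def _combined_scores(
    ihc_scores: pd.DataFrame, fallback: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IHC score matrix with per-cell mRNA fallback where IHC is missing."""
    if fallback is None or fallback.empty:
        return ihc_scores, pd.DataFrame(
            "ihc", index=ihc_scores.index, columns=ihc_scores.columns
        )
    genes = ihc_scores.index.union(fallback.index)
    cols = ihc_scores.columns.union(fallback.columns)
    ihc = ihc_scores.reindex(index=genes, columns=cols)
    mrna = fallback.reindex(index=genes, columns=cols)
    combined = ihc.where(ihc.notna(), mrna)
    source = pd.DataFrame("ihc", index=genes, columns=cols).where(
        ihc.notna(), "mrna"
    )
    return combined, source


def filter_tumor_quasi_h(
    pathology: pd.DataFrame,
    genes: Iterable[str],
    threshold: float = 150.0,
    fallback_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FilterResult]:
    """Keep genes scoring strictly above ``threshold`` in >= 1 tumor type.

    IHC-derived scores are used; where a gene x cancer IHC record is missing
    and ``fallback_scores`` (mRNA-derived) covers the cell, the fallback value
    stands in.  Returns the passing (gene, cancer_type, score, source)
    target-indication table and the filter result.
    """
    if not 0.0 <= threshold <= 300.0:
        raise ConfigError(f"quasi H threshold {threshold} outside [0, 300]")
    scores = ihc_quasi_h_table(pathology)
    combined, source = _combined_scores(scores, fallback_scores)
    kept, dropped, indications = [], {}, []
    for g in genes:
        if g not in combined.index or combined.loc[g].dropna().empty:
            dropped[g] = "no tumor data"
            continue
        row = combined.loc[g].dropna()
        passing = row[row > threshold]
        if passing.empty:
            dropped[g] = f"max quasi H-score {row.max():.1f} <= {threshold:g}"
            continue
        kept.append(g)
        for cancer, score in passing.items():
            indications.append(
                {
                    "gene": g,
                    "cancer_type": cancer,
                    "score": float(score),
                    "source": source.loc[g, cancer],
                }
            )
    table = pd.DataFrame(indications, columns=["gene", "cancer_type", "score", "source"])
    return table, FilterResult(kept, dropped)


def filter_surfaceome(genes: Iterable[str], annotations: pd.DataFrame) -> FilterResult:
    flag = _ann_lookup(annotations, "is_surfaceome")
    kept, dropped = [], {}
    for g in genes:
        if bool(flag.get(g, False)):
            kept.append(g)
        else:
            dropped[g] = "not in surfaceome"
    return FilterResult(kept, dropped)


def filter_dual_quasi_h(
    genes: Iterable[str],
    ihc_scores: pd.DataFrame,
    mrna_scores: pd.DataFrame,
    threshold: float = 150.0,
) -> FilterResult:
    """Stage 6b: require quasi H > threshold in both IHC and tumor-mRNA scores.

    A gene passes iff some tumor type clears the threshold in both score
    matrices (missing IHC cells fall back to the mRNA score).  Genes absent
    from the tumor expression matrix cannot be cross-checked and are dropped.
    """
    combined, _ = _combined_scores(ihc_scores, mrna_scores)
    kept, dropped = [], {}
    for g in genes:
        if g not in mrna_scores.index or mrna_scores.loc[g].dropna().empty:
            dropped[g] = "absent from tumor mRNA data"
            continue
        if g not in combined.index:
            dropped[g] = "no tumor data"
            continue
        both = pd.concat(
            [combined.loc[g].rename("ihc"), mrna_scores.loc[g].rename("mrna")], axis=1
        ).dropna()
        ok = (both["ihc"] > threshold) & (both["mrna"] > threshold)
        if ok.any():
            kept.append(g)
        else:
            dropped[g] = (
                f"no tumor type with quasi H-score > {threshold:g} in both IHC and mRNA"
            )
    return FilterResult(kept, dropped)


def filter_hsc_mpp(
    hema: ExpressionMatrix,
    genes: Iterable[str],
    hsc_mpp_samples: Iterable[str],
) -> tuple[FilterResult, dict[str, Level]]:
    """Drop genes highly expressed on HSC / multipotent progenitor cells.

    Q1/Q3 are computed over the entire hematopoietic matrix (all genes x all
    samples); a gene's HSC/MPP level is the three-level category of the mean
    of its HSC/MPP-sample values against those global quartiles.  Genes at
    high are dropped; genes absent from the study are dropped as untestable.
    Returns the filter result plus retained genes' medium/low labels.
    """
    hsc_samples = list(hsc_mpp_samples)
    if not hsc_samples:
        raise ConfigError("no HSC/MPP samples designated")
    missing = [s for s in hsc_samples if s not in hema.values.columns]
    if missing:
        raise ConfigError(f"HSC/MPP samples absent from hematopoietic matrix: {missing}")
    all_values = hema.values.to_numpy(float).ravel()
    q1, q3 = np.quantile(all_values, [0.25, 0.75])
    kept, dropped, labels = [], {}, {}
    for g in genes:
        if g not in hema.values.index:
            dropped[g] = "absent from hematopoietic study"
            continue
        mean = float(hema.values.loc[g, hsc_samples].mean())
        if mean < q1:
            level = Level.LOW
        elif mean <= q3:
            level = Level.MEDIUM
        else:
            level = Level.HIGH
        if level == Level.HIGH:
            dropped[g] = "high expression on HSC/MPP cells"
        else:
            kept.append(g)
            labels[g] = level
    return FilterResult(kept, dropped), labels


def evidence_score(annotations: pd.DataFrame) -> pd.Series:
    """Per-gene evidence score 0-5: the count of satisfied evidence criteria."""
    cols = ["literature", "antibody", "protein_family", "preclinical", "clinical"]
    return annotations.set_index("gene")[cols].astype(int).sum(axis=1)


def filter_evidence(genes: Iterable[str], annotations: pd.DataFrame) -> tuple[FilterResult, pd.Series]:
    """Drop genes meeting none of the five evidence criteria."""
    scores = evidence_score(annotations)
    kept, dropped = [], {}
    for g in genes:
        if int(scores.get(g, 0)) > 0:
            kept.append(g)
        else:
            dropped[g] = "no evidence criteria met"
    return FilterResult(kept, dropped), scores


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class CascadeConfig:
    quasi_h_threshold: float = 150.0
    consistency_policy: str = "within_one"
    critical_tissues: tuple[str, ...] = CRITICAL_TISSUES
    hsc_mpp_samples: tuple[str, ...] = ()

    def validate(self) -> None:
        if not 0.0 <= self.quasi_h_threshold <= 300.0:
            raise ConfigError(
                f"quasi H threshold {self.quasi_h_threshold} outside [0, 300]"
            )
        if self.consistency_policy not in ("within_one", "exact"):
            raise ConfigError(f"unknown consistency policy {self.consistency_policy!r}")


@dataclass
class CascadeResult:
    prioritized: list[str]
    indications: pd.DataFrame        # passing (gene, cancer_type, score, source), stage 4
    ihc_scores: pd.DataFrame         # gene x cancer quasi H (IHC)
    mrna_scores: pd.DataFrame        # gene x cohort quasi H (tumor mRNA)
    evidence_scores: pd.Series
    hsc_levels: dict[str, Level] = field(default_factory=dict)
    trace: CascadeTrace = field(default_factory=CascadeTrace)

    @property
    def final_indications(self) -> pd.DataFrame:
        """Target-indication pairs restricted to prioritized survivors."""
        if self.indications.empty:
            return self.indications
        return self.indications[self.indications["gene"].isin(self.prioritized)].reset_index(
            drop=True
        )


def run_cascade(
    annotations: pd.DataFrame,
    normal_ihc: pd.DataFrame,
    pathology: pd.DataFrame,
    tumor_expr: ExpressionMatrix | None,
    normal_mrna: ExpressionMatrix | None,
    hema: ExpressionMatrix | None,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run the full nine-stage cascade and record a per-stage trace."""
    config = config or CascadeConfig()
    config.validate()
    universe = list(annotations["gene"])
    trace = CascadeTrace(n_initial=len(universe))

    res = filter_membrane(annotations, universe)
    genes = trace.add_stage("membrane", res.kept, res.dropped)

    res = filter_protein_evidence(annotations, genes)
    genes = trace.add_stage("protein_evidence", res.kept, res.dropped)

    if genes:
        res = filter_critical_normal(normal_ihc, genes, config.critical_tissues)
    else:
        res = FilterResult([], {})
    genes = trace.add_stage("critical_normal", res.kept, res.dropped)

    mrna_scores = (
        mrna_quasi_h_table(tumor_expr) if tumor_expr is not None else pd.DataFrame()
    )
    indications, res = filter_tumor_quasi_h(
        pathology, genes, config.quasi_h_threshold, fallback_scores=mrna_scores
    )
    genes = trace.add_stage("tumor_quasi_h", res.kept, res.dropped)

    res = filter_surfaceome(genes, annotations)
    genes = trace.add_stage("surfaceome", res.kept, res.dropped)

    if normal_mrna is not None and genes:
        mrna_cats = mrna_tissue_categories(normal_mrna)
        ihc_cats = ihc_tissue_categories(normal_ihc)
        res = check_consistency_6a(mrna_cats, ihc_cats, genes, config.consistency_policy)
    else:
        res = FilterResult(list(genes), {})
    genes = trace.add_stage("mrna_ihc_consistency", res.kept, res.dropped)

    ihc_scores = ihc_quasi_h_table(pathology)
    res = filter_dual_quasi_h(genes, ihc_scores, mrna_scores, config.quasi_h_threshold)
    genes = trace.add_stage("dual_quasi_h", res.kept, res.dropped)

    hsc_levels: dict[str, Level] = {}
    if hema is not None and genes:
        res, hsc_levels = filter_hsc_mpp(hema, genes, config.hsc_mpp_samples)
    else:
        res = FilterResult(list(genes), {})
    genes = trace.add_stage("hsc_mpp", res.kept, res.dropped)

    res, scores = filter_evidence(genes, annotations)
    genes = trace.add_stage("evidence", res.kept, res.dropped)

    return CascadeResult(
        prioritized=genes,
        indications=indications,
        ihc_scores=ihc_scores,
        mrna_scores=mrna_scores,
        evidence_scores=scores,
        hsc_levels=hsc_levels,
        trace=trace,
    )
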