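"""Synthetic input bundles with planted ground truth.

Every table kind the pipeline consumes can be generated here with known
structure: "ideal" target genes constructed to survive all nine cascade
stages, one decoy family per stage that fails exactly there, planted
mutation-expression associations with chosen effect sizes and prevalences,
and planted payload sensitivity groups with chosen partition sizes.  The
planted truth is emitted alongside the data so recovery is checkable.

What the generator emulates (and what it does not) is documented in
docs/methods.md; marginal distributions are deliberately simple (Dirichlet
patient fractions, log-normal abundances, truncated-normal inactive GI50s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .cascade import (
    CRITICAL_TISSUES,
    DEFAULT_TUMOR_TYPES,
    NORMAL_TISSUES,
    categorize_quartiles,
)
from .io import ConfigError, ExpressionMatrix, Level, write_table

__all__ = [
    "PlantedTruth",
    "TargetBundle",
    "MutationBundle",
    "PayloadBundle",
    "AssociationSpec",
    "GroupSpec",
    "CASCADE_STAGES",
    "generate_target_inputs",
    "generate_mutation_inputs",
    "generate_gi50_inputs",
    "DEFAULT_LINES_PER_PANEL",
    "HEMA_CELL_TYPES",
]

CASCADE_STAGES = (
    "membrane",
    "protein_evidence",
    "critical_normal",
    "tumor_quasi_h",
    "surfaceome",
    "mrna_ihc_consistency",
    "dual_quasi_h",
    "hsc_mpp",
    "evidence",
)

HEMA_CELL_TYPES = ("HSC", "MPP", "CMP", "GMP", "MEP", "Monocyte", "Neutrophil", "Erythroblast")

#: Cell-line counts of the nine NCI-60 panels.
DEFAULT_LINES_PER_PANEL = {
    "Leukemia": 6,
    "Non-Small Cell Lung Cancer": 9,
    "Colon Cancer": 7,
    "CNS Cancer": 6,
    "Melanoma": 9,
    "Ovarian Cancer": 7,
    "Renal Cancer": 8,
    "Prostate Cancer": 2,
    "Breast Cancer": 6,
}


class AssociationSpec(NamedTuple):
    target: str
    query: str
    cohort: str
    log2_fc: float
    fraction: float


@dataclass
class GroupSpec:
    """Planted payload group sizes (defaults mirror the study's funnel)."""

    pico_only: int = 33
    nano_only: int = 631
    overlap: int = 65
    failed_pico: int = 93
    failed_nano: int = 1616

    @property
    def total(self) -> int:
        return self.pico_only + self.nano_only + self.overlap + self.failed_pico + self.failed_nano


@dataclass
class PlantedTruth:
    ideal_targets: list[str] = field(default_factory=list)
    decoys: dict[str, list[str]] = field(default_factory=dict)
    planted_associations: list[dict] = field(default_factory=list)
    payload_groups: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ideal_targets": self.ideal_targets,
            "decoys": self.decoys,
            "planted_associations": self.planted_associations,
            "payload_groups": self.payload_groups,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TargetBundle:
    annotations: pd.DataFrame
    normal_ihc: pd.DataFrame
    pathology: pd.DataFrame
    tumor: ExpressionMatrix
    normal_mrna: ExpressionMatrix
    hema: ExpressionMatrix
    hsc_mpp_samples: tuple[str, ...]
    truth: PlantedTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_annotation": write_table(self.annotations, out / "gene_annotation.tsv"),
            "normal_tissue": write_table(self.normal_ihc, out / "normal_tissue.tsv"),
            "pathology": write_table(self.pathology, out / "pathology.tsv"),
        }
        for name, mat in (
            ("tumor_expression", self.tumor),
            ("normal_mrna", self.normal_mrna),
            ("hematopoietic", self.hema),
        ):
            p = out / f"{name}.tsv"
            mat.write(p)
            paths[name] = p
        (out / "hsc_mpp_samples.json").write_text(json.dumps(list(self.hsc_mpp_samples)))
        self.truth.write(out / "truth.json")
        return paths


@dataclass
class MutationBundle:
    expression: ExpressionMatrix
    mutations: pd.DataFrame
    truth: PlantedTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p_expr = out / "mutation_expression.tsv"
        self.expression.write(p_expr)
        p_mut = write_table(self.mutations, out / "mutations.tsv")
        self.truth.write(out / "mutation_truth.json")
        return {"expression": p_expr, "mutations": p_mut}


@dataclass
class PayloadBundle:
    measurements: pd.DataFrame
    truth: PlantedTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = write_table(self.measurements, out / "gi50.tsv")
        self.truth.write(out / "payload_truth.json")
        return {"gi50": p}


# ---------------------------------------------------------------------------
# target-arm bundle
# ---------------------------------------------------------------------------


def _empty_target_bundle() -> TargetBundle:
    empty_matrix = ExpressionMatrix(
        values=pd.DataFrame(dtype=float), cohort_of=pd.Series(dtype=object), unit="TPM"
    )
    return TargetBundle(
        annotations=pd.DataFrame(
            columns=[
                "gene", "is_membrane", "has_protein_evidence", "is_surfaceome",
                "literature", "antibody", "protein_family", "preclinical", "clinical",
            ]
        ),
        normal_ihc=pd.DataFrame(columns=["gene", "tissue", "cell_type", "level"]),
        pathology=pd.DataFrame(
            columns=["gene", "cancer_type", "frac_low", "frac_medium", "frac_high"]
        ),
        tumor=empty_matrix,
        normal_mrna=ExpressionMatrix(
            values=pd.DataFrame(dtype=float), cohort_of=pd.Series(dtype=object), unit="TPM"
        ),
        hema=ExpressionMatrix(
            values=pd.DataFrame(dtype=float), cohort_of=pd.Series(dtype=object), unit="AU"
        ),
        hsc_mpp_samples=(),
        truth=PlantedTruth(),
    )


def _high_pathology_row(rng: np.random.Generator) -> tuple[float, float, float]:
    """Fractions guaranteeing quasi H-score > 165 (frac_high alone >= 55)."""
    high = rng.uniform(55.0, 90.0)
    med = rng.uniform(0.0, (100.0 - high) * 0.6)
    low = rng.uniform(0.0, 100.0 - high - med)
    return low, med, high


def _low_pathology_row(rng: np.random.Generator) -> tuple[float, float, float]:
    """Fractions guaranteeing quasi H-score <= 100 in every draw."""
    return rng.uniform(0, 30), rng.uniform(0, 20), rng.uniform(0, 10)


def _background_pathology_row(rng: np.random.Generator) -> tuple[float, float, float]:
    nd, low, med, high = rng.dirichlet((2.0, 2.0, 1.5, 1.0)) * 100.0
    return low, med, high


def generate_target_inputs(
    n_genes: int = 500,
    n_cancer_types: int = 20,
    n_tissues: int = 44,
    seed: int = 0,
    *,
    n_ideal: int = 10,
    decoy_family_size: int = 5,
    samples_per_cohort: int = 30,
    hema_replicates: int = 3,
    zero_rate: float = 0.1,
) -> TargetBundle:
    """Generate the full target-arm input bundle with planted truth.

    ``n_ideal`` genes are constructed to survive every cascade stage;
    ``decoy_family_size`` genes per stage violate exactly that stage; the
    rest are unconstrained background.
    """
    if n_genes == 0:
        return _empty_target_bundle()
    if n_genes < 0:
        raise ConfigError("n_genes must be >= 0")
    n_planted = n_ideal + decoy_family_size * len(CASCADE_STAGES)
    if n_genes < n_planted:
        raise ConfigError(
            f"n_genes={n_genes} smaller than planted+decoy count {n_planted}"
        )
    rng = np.random.default_rng(seed)

    tissues = list(NORMAL_TISSUES[:n_tissues])
    if len(tissues) < n_tissues:
        tissues += [f"tissue_{i}" for i in range(len(tissues), n_tissues)]
    critical = [t for t in tissues if t in CRITICAL_TISSUES]
    noncritical = [t for t in tissues if t not in CRITICAL_TISSUES]
    if not critical:
        raise ConfigError("tissue list contains no critical tissue")
    if len(noncritical) < n_tissues // 4 + 1:
        raise ConfigError("too few non-critical tissues to place high categories safely")

    cancers = list(DEFAULT_TUMOR_TYPES[:n_cancer_types])
    if len(cancers) < n_cancer_types:
        cancers += [f"CT{i:02d}" for i in range(len(cancers), n_cancer_types)]

    genes = [f"G{i:05d}" for i in range(n_genes)]
    roles: dict[str, str] = {}
    cursor = 0
    ideal = genes[:n_ideal]
    for g in ideal:
        roles[g] = "ideal"
    cursor = n_ideal
    decoys: dict[str, list[str]] = {}
    for stage in CASCADE_STAGES:
        fam = genes[cursor : cursor + decoy_family_size]
        decoys[stage] = fam
        for g in fam:
            roles[g] = stage
        cursor += decoy_family_size
    for g in genes[cursor:]:
        roles[g] = "background"

    planted_set = {g for g, r in roles.items() if r != "background"}

    # --- annotations -------------------------------------------------------
    ann_rows = []
    for g in genes:
        role = roles[g]
        if role == "background":
            flags = {
                "is_membrane": rng.random() < 0.5,
                "has_protein_evidence": rng.random() < 0.8,
                "is_surfaceome": rng.random() < 0.3,
            }
            ev = rng.random(5) < 0.2
        else:
            flags = {
                "is_membrane": role != "membrane",
                "has_protein_evidence": role != "protein_evidence",
                "is_surfaceome": role != "surfaceome",
            }
            ev = rng.random(5) < 0.4
            if role == "evidence":
                ev = np.zeros(5, dtype=bool)
            elif not ev.any():
                ev[0] = True
        ann_rows.append(
            {
                "gene": g,
                **flags,
                "literature": bool(ev[0]),
                "antibody": bool(ev[1]),
                "protein_family": bool(ev[2]),
                "preclinical": bool(ev[3]),
                "clinical": bool(ev[4]),
            }
        )
    annotations = pd.DataFrame(ann_rows)

    # --- normal tissue: mRNA values and concordant IHC ---------------------
    mrna_rows = {}
    ihc_rows = []
    crit_order = list(critical)
    for g in genes:
        role = roles[g]
        values = rng.lognormal(1.0, 1.0, n_tissues)
        if role == "background":
            zeros = rng.random(n_tissues) < zero_rate
            values = np.where(zeros, 0.0, values)
            order = list(tissues)
            tissue_values = dict(zip(order, values))
        else:
            # keep high categories out of critical tissues: the 13 smallest
            # values go to critical tissues, the rest to non-critical ones
            values = np.sort(values)[::-1]
            order = list(noncritical) + crit_order
            tissue_values = dict(zip(order, values))
        vec = np.array([tissue_values[t] for t in tissues])
        mrna_rows[g] = vec
        cats = categorize_quartiles(vec, "four_level")
        cat_of = dict(zip(tissues, cats))
        if role == "background":
            noise = rng.integers(-1, 2, n_tissues)
            flip = rng.random(n_tissues) < 0.2
            for i, t in enumerate(tissues):
                if flip[i]:
                    cat_of[t] = int(np.clip(cat_of[t] + noise[i], 0, 3))
        if role == "critical_normal":
            cat_of[critical[int(rng.integers(len(critical)))]] = int(Level.HIGH)
        if role == "mrna_ihc_consistency":
            # an IHC call contradicting the mRNA category by >= 2 levels
            t_max = max(noncritical, key=lambda t: tissue_values[t])
            cat_of[t_max] = int(Level.NOT_DETECTED)
        for t in tissues:
            ihc_rows.append(
                {
                    "gene": g,
                    "tissue": t,
                    "cell_type": f"{t} cells",
                    "level": Level(int(cat_of[t])).label,
                }
            )
    normal_ihc = pd.DataFrame(ihc_rows)
    normal_ihc["level"] = pd.Categorical(
        normal_ihc["level"], categories=[lv.label for lv in Level], ordered=True
    )
    normal_mrna = ExpressionMatrix(
        values=pd.DataFrame.from_dict(mrna_rows, orient="index", columns=tissues),
        cohort_of=pd.Series(tissues, index=tissues),
        unit="nTPM",
    )

    # --- pathology ---------------------------------------------------------
    path_rows = []
    for g in genes:
        role = roles[g]
        if role in ("ideal", "surfaceome", "mrna_ihc_consistency", "dual_quasi_h",
                    "hsc_mpp", "evidence", "membrane", "protein_evidence", "critical_normal"):
            n_high = int(rng.integers(1, 4))
            high_cancers = set(rng.choice(cancers, size=n_high, replace=False))
            for c in cancers:
                if c in high_cancers:
                    low, med, high = _high_pathology_row(rng)
                else:
                    low, med, high = _background_pathology_row(rng)
                path_rows.append(
                    {"gene": g, "cancer_type": c, "frac_low": low, "frac_medium": med, "frac_high": high}
                )
        elif role == "tumor_quasi_h":
            for c in cancers:
                low, med, high = _low_pathology_row(rng)
                path_rows.append(
                    {"gene": g, "cancer_type": c, "frac_low": low, "frac_medium": med, "frac_high": high}
                )
        else:  # background, with occasional missing gene x cancer records
            for c in cancers:
                if rng.random() < 0.1:
                    continue
                low, med, high = _background_pathology_row(rng)
                path_rows.append(
                    {"gene": g, "cancer_type": c, "frac_low": low, "frac_medium": med, "frac_high": high}
                )
    pathology = pd.DataFrame(path_rows)

    # --- tumor expression matrix (cohort-labelled) -------------------------
    samples, cohort_labels = [], []
    for c in cancers:
        for i in range(samples_per_cohort):
            samples.append(f"{c}_{i:03d}")
            cohort_labels.append(c)
    matrix_genes = [g for g in genes if roles[g] != "dual_quasi_h"]
    tumor_values = rng.lognormal(1.0, 1.0, (len(matrix_genes), len(samples)))
    tumor = ExpressionMatrix(
        values=pd.DataFrame(tumor_values, index=matrix_genes, columns=samples),
        cohort_of=pd.Series(cohort_labels, index=samples),
        unit="FPKM",
    )

    # --- hematopoietic matrix ----------------------------------------------
    hema_samples = [f"{ct}_{r + 1}" for ct in HEMA_CELL_TYPES for r in range(hema_replicates)]
    hsc_mpp = tuple(
        s for s in hema_samples if s.startswith("HSC_") or s.startswith("MPP_")
    )
    hema_genes = []
    for g in genes:
        if roles[g] == "background" and rng.random() < 0.05:
            continue  # absent from the hematopoietic study
        hema_genes.append(g)
    hema_values = rng.lognormal(1.0, 1.0, (len(hema_genes), len(hema_samples)))
    hema_df = pd.DataFrame(hema_values, index=hema_genes, columns=hema_samples)
    q1, q3 = np.quantile(hema_df.to_numpy(float).ravel(), [0.25, 0.75])
    mid = 0.5 * (q1 + q3)
    low_val = 0.5 * q1
    high_val = 2.0 * q3 + 1.0
    low_flags = rng.random(len(genes)) < (1.0 / 3.0)
    for i, g in enumerate(genes):
        role = roles[g]
        if role == "background" or g not in hema_df.index:
            continue
        if role == "hsc_mpp":
            hema_df.loc[g, list(hsc_mpp)] = high_val
        else:
            hema_df.loc[g, list(hsc_mpp)] = low_val if low_flags[i] else mid
    hema = ExpressionMatrix(
        values=hema_df,
        cohort_of=pd.Series(
            [s.rsplit("_", 1)[0] for s in hema_samples], index=hema_samples
        ),
        unit="AU",
    )

    truth = PlantedTruth(ideal_targets=list(ideal), decoys=decoys)
    return TargetBundle(
        annotations=annotations,
        normal_ihc=normal_ihc,
        pathology=pathology,
        tumor=tumor,
        normal_mrna=normal_mrna,
        hema=hema,
        hsc_mpp_samples=hsc_mpp,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# mutation-arm bundle
# ---------------------------------------------------------------------------


def generate_mutation_inputs(
    cohorts: Iterable[str],
    n_samples_per_cohort: int,
    planted: Iterable[AssociationSpec],
    seed: int = 0,
    *,
    targets: Iterable[str] | None = None,
    queries: Iterable[str] | None = None,
    meanlog: float = 4.0,
    sdlog: float = 0.5,
) -> MutationBundle:
    """Cohort-labelled expression plus mutation calls with planted effects.

    Wild-type expression is log-normal (``meanlog``, ``sdlog``); samples
    carrying a planted mutation have the target's expression scaled by
    ``2**log2_fc``; carrier status is Bernoulli at the planted fraction.
    """
    cohorts = list(dict.fromkeys(cohorts))
    planted = [AssociationSpec(*p) for p in planted]
    if n_samples_per_cohort < 2:
        raise ConfigError("each cohort needs at least 2 samples")
    for spec in planted:
        if not 0.0 < spec.fraction < 1.0:
            raise ConfigError(f"mutated fraction {spec.fraction} outside (0, 1)")
        if not np.isfinite(spec.log2_fc):
            raise ConfigError("planted log2 fold change must be finite")
        if spec.cohort not in cohorts:
            raise ConfigError(f"planted cohort {spec.cohort!r} not in cohort list")
    rng = np.random.default_rng(seed)

    targets = list(dict.fromkeys(
        list(targets) if targets is not None else [s.target for s in planted]
    ))
    queries = list(dict.fromkeys(
        list(queries) if queries is not None else [s.query for s in planted]
    ))

    samples, labels = [], []
    for c in cohorts:
        for i in range(n_samples_per_cohort):
            samples.append(f"{c}_{i:04d}")
            labels.append(c)
    values = rng.lognormal(meanlog, sdlog, (len(targets), len(samples)))
    expr_df = pd.DataFrame(values, index=targets, columns=samples)
    cohort_of = pd.Series(labels, index=samples)

    mut_rows = []
    for c in cohorts:
        cohort_samples = [s for s, lb in zip(samples, labels) if lb == c]
        for q in queries:
            specs = [s for s in planted if s.query == q and s.cohort == c]
            fraction = specs[0].fraction if specs else 0.0
            if fraction <= 0.0:
                continue
            carriers = [s for s in cohort_samples if rng.random() < fraction]
            for s in carriers:
                mut_rows.append({"sample": s, "gene": q})
            for spec in specs:
                expr_df.loc[spec.target, carriers] *= 2.0 ** spec.log2_fc
    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene"])

    truth = PlantedTruth(
        planted_associations=[
            {
                "target": s.target,
                "query_gene": s.query,
                "cohort": s.cohort,
                "log2_fc": s.log2_fc,
                "fraction": s.fraction,
            }
            for s in planted
        ]
    )
    expr = ExpressionMatrix(values=expr_df, cohort_of=cohort_of, unit="TPM")
    return MutationBundle(expression=expr, mutations=mutations, truth=truth)


# ---------------------------------------------------------------------------
# payload-arm bundle
# ---------------------------------------------------------------------------


def _inactive(rng: np.random.Generator, size: int) -> np.ndarray:
    """Inactive-compound log10 GI50 values: N(-6, 1) floored at -7.8.

    The floor keeps inactive lines clear of the 10 nM cutoff so that planted
    group membership is exact at any seed.
    """
    return np.maximum(rng.normal(-6.0, 1.0, size), -7.8)


def generate_gi50_inputs(
    n_compounds: int = 3000,
    lines_per_panel: dict[str, int] | None = None,
    planted: GroupSpec | None = None,
    seed: int = 0,
    *,
    payload_names: Iterable[str] = (),
    n_duplicate_pairs: int = 5,
    replicate_rate: float = 0.05,
) -> PayloadBundle:
    """GI50 measurement table with planted sensitivity groups.

    Planted picomolar compounds are responsive (GI50 <= 1 nM) in >= 50% of
    lines of at least one panel; low-nanomolar compounds likewise within
    (1, 10] nM; overlap compounds carry both patterns in two panels.  Failed
    compounds qualify but carry the failed-screen flag; duplicate-name pairs
    exercise dedupe.  ``payload_names`` are assigned to the first
    low-nanomolar compounds with a fully (100%) responsive panel each.
    """
    lines_per_panel = dict(lines_per_panel or DEFAULT_LINES_PER_PANEL)
    planted = planted or GroupSpec()
    payload_names = list(payload_names)
    for panel, n in lines_per_panel.items():
        if n <= 0:
            raise ConfigError(f"panel {panel!r} has no cell lines; response undefined")
    if len(payload_names) > planted.nano_only:
        raise ConfigError("more payload names than planted low-nanomolar compounds")
    n_planted = planted.total
    if n_compounds < n_planted + 2 * n_duplicate_pairs:
        raise ConfigError(
            f"n_compounds={n_compounds} too small for {n_planted} planted compounds "
            f"and {n_duplicate_pairs} duplicate pairs"
        )
    rng = np.random.default_rng(seed)
    panels = list(lines_per_panel)
    lines = {
        p: [f"{''.join(w[0] for w in p.split())}-{i + 1}" for i in range(lines_per_panel[p])]
        for p in panels
    }

    roles: list[str] = (
        ["pico_only"] * planted.pico_only
        + ["nano_only"] * planted.nano_only
        + ["overlap"] * planted.overlap
        + ["failed_pico"] * planted.failed_pico
        + ["failed_nano"] * planted.failed_nano
    )
    roles += ["background"] * (n_compounds - len(roles))

    nano_seen = 0
    rows = []
    truth_groups: dict[str, list[int]] = {
        "picomolar_only": [],
        "low_nanomolar_only": [],
        "overlap": [],
        "failed": [],
        "duplicate_pairs": [],
    }
    n_background = roles.count("background")
    dup_originals = {}  # background ordinal -> duplicate-of ordinal
    if n_duplicate_pairs:
        # first k background compounds are originals, next k their duplicates
        for j in range(n_duplicate_pairs):
            dup_originals[n_duplicate_pairs + j] = j
    background_seen = 0
    background_names: dict[int, str] = {}

    def active_values(window: str, n_lines: int) -> np.ndarray:
        n_resp = max(1, int(np.ceil(rng.uniform(0.5, 1.0) * n_lines)))
        vals = _inactive(rng, n_lines)
        if window == "pico":
            vals[:n_resp] = rng.uniform(-11.0, -9.2, n_resp)
        else:
            vals[:n_resp] = rng.uniform(-8.95, -8.05, n_resp)
        return rng.permutation(vals)

    for ordinal, role in enumerate(roles):
        nsc = ordinal + 1
        name = f"cpd-{nsc}"
        failed = role.startswith("failed")
        status = ("none", "clinical", "fda_approved")[
            int(rng.choice(3, p=(0.95, 0.03, 0.02)))
        ]
        values: dict[str, np.ndarray] = {p: _inactive(rng, lines_per_panel[p]) for p in panels}
        if role in ("pico_only", "failed_pico"):
            panel = panels[int(rng.integers(len(panels)))]
            values[panel] = active_values("pico", lines_per_panel[panel])
        elif role in ("nano_only", "failed_nano"):
            if role == "nano_only" and nano_seen < len(payload_names):
                name = payload_names[nano_seen]
                panel = panels[nano_seen % len(panels)]
                values[panel] = rng.uniform(-8.95, -8.05, lines_per_panel[panel])
            else:
                panel = panels[int(rng.integers(len(panels)))]
                values[panel] = active_values("nano", lines_per_panel[panel])
            if role == "nano_only":
                nano_seen += 1
        elif role == "overlap":
            p1, p2 = rng.choice(len(panels), size=2, replace=False)
            values[panels[p1]] = active_values("pico", lines_per_panel[panels[p1]])
            values[panels[p2]] = active_values("nano", lines_per_panel[panels[p2]])
        else:  # background
            if background_seen in dup_originals:
                orig_ordinal = dup_originals[background_seen]
                orig_name = background_names[orig_ordinal]
                name = orig_name.upper() + " "
                truth_groups["duplicate_pairs"].append(nsc)
            elif rng.random() < 0.5 or background_seen < n_duplicate_pairs:
                background_names[background_seen] = name
            else:
                name = ""
            background_seen += 1
        if role == "pico_only":
            truth_groups["picomolar_only"].append(nsc)
        elif role == "nano_only":
            truth_groups["low_nanomolar_only"].append(nsc)
        elif role == "overlap":
            truth_groups["overlap"].append(nsc)
        elif failed:
            truth_groups["failed"].append(nsc)
        for p in panels:
            for line, v in zip(lines[p], values[p]):
                rows.append(
                    {
                        "nsc_id": nsc,
                        "name": name,
                        "cell_line": line,
                        "panel": p,
                        "log_gi50": float(v),
                        "failed_screen": failed,
                        "status": status,
                    }
                )
                if rng.random() < replicate_rate:
                    rows.append(
                        {
                            "nsc_id": nsc,
                            "name": name,
                            "cell_line": line,
                            "panel": p,
                            "log_gi50": float(v + rng.uniform(-0.02, 0.02)),
                            "failed_screen": failed,
                            "status": status,
                        }
                    )
    measurements = pd.DataFrame(
        rows,
        columns=["nsc_id", "name", "cell_line", "panel", "log_gi50", "failed_screen", "status"],
    )
    truth = PlantedTruth(payload_groups=truth_groups)
    return PayloadBundle(measurements=measurements, truth=truth)
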