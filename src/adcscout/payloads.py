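"""GI50 mining for tumor-selective cytotoxic payload candidates.

The workflow mirrors the compound-screening funnel: duplicate compound names
are merged, replicate measurements per cell line are averaged (mean of log10
GI50, i.e. geometric-mean potency), compounds are grouped into a picomolar
class (GI50 <= 1 nM) and a low-nanomolar class (1 nM < GI50 <= 10 nM) based
on where their per-line potencies fall, and each class keeps compounds with
>= 50% responsive lines in at least one of the nine NCI-60 indication panels.
Compounds flagged as failed NCI-60 screens are then removed, the survivors
are partitioned into picomolar-only / low-nanomolar-only / overlap groups,
and each group's per-panel response profile is clustered (Ward linkage,
Euclidean distance).

A compound enters a sensitivity class iff it has at least one aggregated
line-level GI50 inside that class's band; the response percentage within a
class counts lines at or below the class ceiling (<= 1 nM for picomolar,
<= 10 nM for low nanomolar), so a line killed at picomolar dose also counts
as responsive at 10 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import CascadeTrace, ConfigError, NCI60_PANELS

__all__ = [
    "PICOMOLAR_CUTOFF_LOG",
    "LOW_NANOMOLAR_CUTOFF_LOG",
    "dedupe_compounds",
    "aggregate_replicates",
    "classify_sensitivity",
    "response_profiles",
    "drop_failed",
    "partition_groups",
    "cluster_profiles",
    "cumulative_response",
    "PayloadConfig",
    "PayloadResult",
    "run_payload_pipeline",
]

#: log10 molar GI50 at 1 nM — ceiling of the picomolar class.
PICOMOLAR_CUTOFF_LOG = -9.0
#: log10 molar GI50 at 10 nM — ceiling of the low-nanomolar class.
LOW_NANOMOLAR_CUTOFF_LOG = -8.0


def _normalize_name(name: str) -> str:
    return str(name).strip().casefold()


def dedupe_compounds(measurements: pd.DataFrame) -> pd.DataFrame:
    """Merge compounds sharing a normalized name under the smallest NSC id.

    Name normalization trims whitespace and casefolds.  Unnamed compounds are
    keyed by NSC id alone and never merged.  Measurements of merged
    duplicates are reassigned to the surviving NSC id.
    """
    df = measurements.copy()
    norm = df["name"].map(_normalize_name)
    named = norm != ""
    canonical_nsc = df.loc[named].assign(_norm=norm[named]).groupby("_norm")["nsc_id"].min()
    name_of = (
        df.loc[named]
        .assign(_norm=norm[named])
        .sort_values("nsc_id")
        .groupby("_norm")["name"]
        .first()
    )
    df.loc[named, "nsc_id"] = norm[named].map(canonical_nsc).astype(df["nsc_id"].dtype)
    df.loc[named, "name"] = norm[named].map(name_of)
    return df.reset_index(drop=True)


def classify_sensitivity(log_gi50: float) -> str:
    """Class of one GI50 value: picomolar (<= 1 nM), low_nanomolar (1-10 nM], none."""
    if not np.isfinite(log_gi50):
        raise ValueError(f"non-finite log GI50 {log_gi50!r}")
    if log_gi50 <= PICOMOLAR_CUTOFF_LOG:
        return "picomolar"
    if log_gi50 <= LOW_NANOMOLAR_CUTOFF_LOG:
        return "low_nanomolar"
    return "none"


def aggregate_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """One row per (compound, panel, cell line): mean log10 GI50 over replicates."""
    agg = (
        measurements.groupby(["nsc_id", "panel", "cell_line"], as_index=False)
        .agg(log_gi50=("log_gi50", "mean"))
    )
    return agg


def compound_annotations(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-compound name / failed flag / best clinical status."""
    status_rank = {"none": 0, "clinical": 1, "fda_approved": 2}
    grouped = measurements.groupby("nsc_id")
    out = pd.DataFrame(
        {
            "name": grouped["name"].agg(lambda s: next((v for v in s if v), "")),
            "failed_screen": grouped["failed_screen"].any(),
            "status": grouped["status"].agg(
                lambda s: max(s, key=lambda v: status_rank.get(v, 0))
            ),
        }
    )
    return out


def _window(sens_class: str) -> tuple[float, float]:
    if sens_class == "picomolar":
        return -np.inf, PICOMOLAR_CUTOFF_LOG
    if sens_class == "low_nanomolar":
        return PICOMOLAR_CUTOFF_LOG, LOW_NANOMOLAR_CUTOFF_LOG
    raise ValueError(f"unknown sensitivity class {sens_class!r}")


def response_profiles(
    measurements: pd.DataFrame,
    sens_class: str,
    threshold_pct: float = 50.0,
    *,
    panels: Iterable[str] = NCI60_PANELS,
    aggregated: bool = False,
) -> pd.DataFrame:
    """Per-panel response percentages for compounds of one sensitivity class.

    Replicates are aggregated first.  A compound belongs to the class iff at
    least one aggregated line falls inside the class band; a line counts as
    responsive when its GI50 is at or below the class ceiling.  Panels with
    no measured line are NaN (missing, not 0).  ``qualifies`` is true when
    any panel reaches ``threshold_pct``.
    """
    panels = list(panels)
    agg = measurements if aggregated else aggregate_replicates(measurements)
    lo, hi = _window(sens_class)
    in_band = (agg["log_gi50"] > lo) & (agg["log_gi50"] <= hi)
    members = set(agg.loc[in_band, "nsc_id"])
    sub = agg[agg["nsc_id"].isin(members)]
    responsive = sub["log_gi50"] <= hi
    counts = (
        sub.assign(_resp=responsive)
        .groupby(["nsc_id", "panel"])
        .agg(n_lines=("_resp", "size"), n_resp=("_resp", "sum"))
        .reset_index()
    )
    counts["pct"] = 100.0 * counts["n_resp"] / counts["n_lines"]
    prof = counts.pivot(index="nsc_id", columns="panel", values="pct")
    prof = prof.reindex(columns=panels)
    prof = prof.rename_axis(index=None, columns=None)
    prof["qualifies"] = prof[panels].max(axis=1, skipna=True) >= threshold_pct
    return prof


def cumulative_response(
    measurements: pd.DataFrame,
    cutoff_log: float = LOW_NANOMOLAR_CUTOFF_LOG,
    *,
    panels: Iterable[str] = NCI60_PANELS,
    compounds: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-panel % of lines with GI50 <= cutoff, regardless of class membership."""
    panels = list(panels)
    agg = aggregate_replicates(measurements)
    if compounds is not None:
        agg = agg[agg["nsc_id"].isin(set(compounds))]
    responsive = agg["log_gi50"] <= cutoff_log
    counts = (
        agg.assign(_resp=responsive)
        .groupby(["nsc_id", "panel"])
        .agg(n_lines=("_resp", "size"), n_resp=("_resp", "sum"))
        .reset_index()
    )
    counts["pct"] = 100.0 * counts["n_resp"] / counts["n_lines"]
    prof = counts.pivot(index="nsc_id", columns="panel", values="pct")
    return prof.reindex(columns=panels).rename_axis(index=None, columns=None)


def drop_failed(profiles: pd.DataFrame, failed: pd.Series | dict) -> pd.DataFrame:
    """Remove failed-screen compounds from a profile table (post response screen)."""
    failed = pd.Series(failed)
    flags = failed.reindex(profiles.index).fillna(False).astype(bool)
    return profiles.loc[~flags]


def partition_groups(pico_qualifiers: Iterable[int], nano_qualifiers: Iterable[int]) -> pd.DataFrame:
    """Partition final compounds into picomolar_only / low_nanomolar_only / overlap."""
    pico = set(pico_qualifiers)
    nano = set(nano_qualifiers)
    rows = [
        {"nsc_id": c, "membership": "overlap"} for c in sorted(pico & nano)
    ] + [
        {"nsc_id": c, "membership": "picomolar_only"} for c in sorted(pico - nano)
    ] + [
        {"nsc_id": c, "membership": "low_nanomolar_only"} for c in sorted(nano - pico)
    ]
    out = pd.DataFrame(rows, columns=["nsc_id", "membership"])
    return out.sort_values("nsc_id", ignore_index=True)


def cluster_profiles(profiles: pd.DataFrame, k: int, *, panels: Iterable[str] = NCI60_PANELS) -> pd.Series:
    """Agglomerative (Ward, Euclidean) clustering of 9-panel response vectors.

    Missing panels are imputed as 0% for distance purposes.  Rows are sorted
    by compound id before linkage so the partition is input-order invariant;
    labels are renumbered 1..k in order of first appearance.
    """
    panels = [p for p in panels if p in profiles.columns]
    if len(profiles) < k:
        raise ValueError(f"cannot cut {len(profiles)} profiles into {k} clusters")
    ordered = profiles.sort_index()
    x = ordered[panels].fillna(0.0).to_numpy(float)
    if k == len(ordered):
        raw = np.arange(1, k + 1)
    else:
        z = linkage(x, method="ward", metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        labels.append(relabel.setdefault(int(r), len(relabel) + 1))
    return pd.Series(labels, index=ordered.index, name="cluster")


@dataclass
class PayloadConfig:
    response_threshold_pct: float = 50.0
    panels: tuple[str, ...] = NCI60_PANELS
    cluster_counts: dict = field(
        default_factory=lambda: {"picomolar_only": 5, "low_nanomolar_only": 10, "overlap": 10}
    )

    def validate(self) -> None:
        if not 0.0 <= self.response_threshold_pct <= 100.0:
            raise ConfigError(
                f"response threshold {self.response_threshold_pct} outside [0, 100]"
            )
        if len(self.panels) == 0:
            raise ConfigError("panel vocabulary must be non-empty")


@dataclass
class PayloadResult:
    groups: pd.DataFrame                  # nsc_id, name, membership, cluster, status
    profiles: dict[str, pd.DataFrame]     # per class: panel response percentages
    annotations: pd.DataFrame             # per-compound name/failed/status
    measurements: pd.DataFrame            # deduped raw measurements
    traces: dict[str, CascadeTrace]
    group_sizes: dict[str, int] = field(default_factory=dict)


def _class_trace(
    name: str,
    n_deduped: int,
    all_ids: Iterable[int],
    profiles: pd.DataFrame,
    qualified: pd.DataFrame,
    survivors: pd.DataFrame,
) -> CascadeTrace:
    trace = CascadeTrace(n_initial=n_deduped)
    members = set(profiles.index)
    trace.add_stage(
        f"{name}_class",
        sorted(members),
        {str(c): "no measurement in class window" for c in all_ids if c not in members},
    )
    q = set(qualified.index)
    trace.add_stage(
        f"{name}_response_screen",
        sorted(q),
        {str(c): "below response threshold in all panels" for c in members - q},
    )
    s = set(survivors.index)
    trace.add_stage(
        f"{name}_failed_removed",
        sorted(s),
        {str(c): "failed NCI60 screening" for c in q - s},
    )
    return trace


def run_payload_pipeline(measurements: pd.DataFrame, config: PayloadConfig | None = None) -> PayloadResult:
    """Full payload funnel: dedupe, class response screens, failure removal,
    three-way partition and per-group clustering."""
    config = config or PayloadConfig()
    config.validate()
    panels = list(config.panels)

    n_input = measurements["nsc_id"].nunique()
    deduped = dedupe_compounds(measurements)
    ann = compound_annotations(deduped)
    all_ids = sorted(ann.index)

    trace_all = CascadeTrace(n_initial=n_input)
    removed = n_input - len(all_ids)
    # duplicate ids merged away are recorded collectively
    dropped_dupes = {}
    orig_ids = set(measurements["nsc_id"])
    for c in sorted(orig_ids - set(all_ids)):
        dropped_dupes[str(c)] = "duplicate compound name"
    assert len(dropped_dupes) == removed
    trace_all.add_stage("dedupe", all_ids, dropped_dupes)

    agg = aggregate_replicates(deduped)
    profiles, qualified, survivors, traces = {}, {}, {}, {"compounds": trace_all}
    for sens_class, short in (("picomolar", "picomolar"), ("low_nanomolar", "low_nanomolar")):
        prof = response_profiles(
            agg,
            sens_class,
            config.response_threshold_pct,
            panels=panels,
            aggregated=True,
        )
        qual = prof[prof["qualifies"]]
        surv = drop_failed(qual, ann["failed_screen"])
        profiles[sens_class] = prof
        qualified[sens_class] = qual
        survivors[sens_class] = surv
        traces[short] = _class_trace(short, len(all_ids), all_ids, prof, qual, surv)

    groups = partition_groups(survivors["picomolar"].index, survivors["low_nanomolar"].index)
    group_sizes = groups["membership"].value_counts().to_dict()
    for key in ("picomolar_only", "low_nanomolar_only", "overlap"):
        group_sizes.setdefault(key, 0)

    # clustering: picomolar-only on the <=1 nM window, the other two groups on
    # the <=10 nM window (the scale their heat maps are drawn at)
    cluster_source = {
        "picomolar_only": profiles["picomolar"],
        "low_nanomolar_only": profiles["low_nanomolar"],
        "overlap": profiles["low_nanomolar"],
    }
    groups["cluster"] = pd.NA
    for membership, k in config.cluster_counts.items():
        ids = groups.loc[groups["membership"] == membership, "nsc_id"]
        if len(ids) == 0:
            continue
        source = cluster_source[membership]
        source = source.loc[[i for i in ids if i in source.index]]
        if membership == "overlap":
            # overlap compounds may lack low-nanomolar-band lines; use the
            # cumulative <=10 nM response for any not covered
            missing = [i for i in ids if i not in source.index]
            if missing:
                extra = cumulative_response(deduped, compounds=missing, panels=panels)
                extra["qualifies"] = True
                source = pd.concat([source, extra])
        k_eff = min(int(k), len(source))
        labels = cluster_profiles(source, k_eff, panels=panels)
        groups.loc[groups["membership"] == membership, "cluster"] = (
            groups.loc[groups["membership"] == membership, "nsc_id"].map(labels)
        )

    groups = groups.merge(
        ann[["name", "status"]], left_on="nsc_id", right_index=True, how="left"
    )
    return PayloadResult(
        groups=groups,
        profiles=profiles,
        annotations=ann,
        measurements=deduped,
        traces=traces,
        group_sizes=group_sizes,
    )
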