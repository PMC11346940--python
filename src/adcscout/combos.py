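"""Join prioritized targets with payload-indication data and mutation context.

A combination record pairs a (target gene, tumor type) whose quasi H-score
clears the selectivity threshold with a clinically characterized payload that
shows 100% responsive cell lines (at the <= 10 nM cutoff) in an NCI-60 panel
mapped to that tumor type.  Screened mutation associations for the same
(target, tumor type) are attached as context.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import pandas as pd

from .io import ConfigError
from .payloads import LOW_NANOMOLAR_CUTOFF_LOG, _normalize_name, cumulative_response

__all__ = [
    "DEFAULT_PANEL_MAPPING",
    "DEFAULT_PAYLOADS",
    "payload_indications",
    "map_indication",
    "match_combinations",
]

#: Shipped NCI-60 panel -> TCGA-style tumor-type-code alignment (overridable).
DEFAULT_PANEL_MAPPING: dict[str, tuple[str, ...]] = {
    "Renal Cancer": ("KIRC",),
    "Breast Cancer": ("BRCA",),
    "Ovarian Cancer": ("OV",),
    "Prostate Cancer": ("PRAD",),
    "Colon Cancer": ("COAD",),
    "Melanoma": ("SKCM",),
    "CNS Cancer": ("GBM", "LGG"),
    "Non-Small Cell Lung Cancer": ("LUAD", "LUSC"),
    "Leukemia": ("LAML",),
}

#: Clinically tested payloads screened for 100%-response indications.
DEFAULT_PAYLOADS = (
    "Dxd",
    "exatecan mesylate",
    "maytansine",
    "monomethyl auristatin E",
    "maytansine deriv",
    "eribulin mesylate",
)


def payload_indications(
    measurements: pd.DataFrame,
    payload_names: Iterable[str] = DEFAULT_PAYLOADS,
    *,
    cutoff_log: float = LOW_NANOMOLAR_CUTOFF_LOG,
    panels=None,
) -> dict[str, set[str]]:
    """Panels where each named payload shows 100% responsive lines (<= cutoff).

    Payload names are resolved by normalized (trimmed, casefolded) match
    against compound names; unresolvable names are excluded with a warning
    entry of an empty set.
    """
    import warnings

    by_norm = {}
    for name in measurements["name"].unique():
        norm = _normalize_name(name)
        if norm:
            by_norm.setdefault(norm, set()).add(name)
    kwargs = {} if panels is None else {"panels": panels}
    out: dict[str, set[str]] = {}
    for payload in payload_names:
        norm = _normalize_name(payload)
        if norm not in by_norm:
            warnings.warn(f"payload {payload!r} not found in compound data; skipped")
            continue
        ids = set(
            measurements.loc[measurements["name"].isin(by_norm[norm]), "nsc_id"]
        )
        prof = cumulative_response(measurements, cutoff_log, compounds=ids, **kwargs)
        pct = prof.max(axis=0)  # one compound expected; max over merged ids
        out[payload] = set(pct.index[pct >= 100.0 - 1e-9])
    return out


def map_indication(
    panel: str, mapping: Mapping[str, Iterable[str]] = DEFAULT_PANEL_MAPPING
) -> set[str]:
    """Tumor-type codes aligned with one NCI-60 panel; empty set if unmapped."""
    import warnings

    if not isinstance(mapping, Mapping):
        raise ConfigError("panel mapping must be a mapping of panel -> tumor codes")
    if panel not in mapping:
        warnings.warn(f"NCI-60 panel {panel!r} has no tumor-type mapping")
        return set()
    codes = mapping[panel]
    if isinstance(codes, str):
        raise ConfigError(f"mapping for panel {panel!r} must be a list of codes")
    return set(codes)


def match_combinations(
    target_indications: pd.DataFrame,
    payload_panels: Mapping[str, Iterable[str]],
    associations: pd.DataFrame | None = None,
    mapping: Mapping[str, Iterable[str]] = DEFAULT_PANEL_MAPPING,
) -> pd.DataFrame:
    """Relational join of target-indications, payload panels and associations.

    Emits one record per (target, tumor_type, payload) where the tumor type
    is mapped from a 100%-response panel of the payload and the (gene, tumor
    type) pair passed the quasi H gate.  All screened associations for the
    (target, tumor type) are attached as a JSON list in ``mutation_context``.
    """
    cols = [
        "target",
        "tumor_type",
        "nci60_panel",
        "payload",
        "target_score",
        "mutation_context",
    ]
    if target_indications.empty or not payload_panels:
        return pd.DataFrame(columns=cols)
    assoc = associations if associations is not None else pd.DataFrame()
    rows = []
    ti = target_indications.set_index(["gene", "cancer_type"])["score"]
    for payload, panels in sorted(payload_panels.items()):
        for panel in sorted(panels):
            for code in sorted(map_indication(panel, mapping)):
                hits = ti[ti.index.get_level_values("cancer_type") == code]
                for (gene, _), score in hits.items():
                    context = []
                    if not assoc.empty:
                        sub = assoc[(assoc["target"] == gene) & (assoc["cohort"] == code)]
                        context = [
                            {
                                "query_gene": r["query_gene"],
                                "log2_fc": round(float(r["log2_fc"]), 6),
                                "p_value": float(r["p_value"]),
                                "direction": r["direction"],
                            }
                            for _, r in sub.iterrows()
                        ]
                    rows.append(
                        {
                            "target": gene,
                            "tumor_type": code,
                            "nci60_panel": panel,
                            "payload": payload,
                            "target_score": float(score),
                            "mutation_context": json.dumps(context),
                        }
                    )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["target", "tumor_type", "payload"], ignore_index=True)
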