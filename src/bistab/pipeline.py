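"""Grouped-timecourse driver: manifests, per-group reports, pooled runs.

Assembles the per-group bistability test into the full study workflow: for
each group (e.g. developmental timepoint) load the matrix, optionally
normalize and log-transform, fit the three models, and emit JSON + TSV
reports plus an across-group summary of (sd along PC1, BIC differences,
verdicts).  A pooled case/control mode concatenates a control group with
each case group and runs the same test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ExpressionGroup,
    geometric_mean_normalize,
    read_expression,
)
from .landau import BIC_THRESHOLD, D_MIN
from .model import BistabilityModel, BistabilityResults

__all__ = ["StudyManifest", "StudyReport", "run_study", "pooled_case_control_run"]

logger = logging.getLogger("bistab")


@dataclass(frozen=True)
class StudyManifest:
    """Configuration for one multi-group study.

    ``groups`` is an ordered list of ``(group_label, path)`` pairs, each
    path a samples x genes CSV/TSV.  ``value_scale`` declares whether the
    files hold raw positive counts (to be natural-log transformed) or
    already log-space values.
    """

    groups: list[tuple[str, str]]
    value_scale: str = "log"
    housekeeping_gene_ids: list[str] | None = None
    threshold: float = BIC_THRESHOLD
    d_min: float = D_MIN
    reference_gene_for_orientation: str | None = None

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if self.value_scale not in ("raw", "log"):
            raise ValueError("value_scale must be 'raw' or 'log'")
        if self.housekeeping_gene_ids and self.value_scale != "raw":
            raise ValueError(
                "housekeeping normalization requires raw-scale input"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            groups=[tuple(g) for g in cfg["groups"]],
            value_scale=cfg.get("value_scale", "log"),
            housekeeping_gene_ids=cfg.get("housekeeping_gene_ids"),
            threshold=cfg.get("threshold", BIC_THRESHOLD),
            d_min=cfg.get("d_min", D_MIN),
            reference_gene_for_orientation=cfg.get("reference_gene_for_orientation"),
        )


@dataclass
class StudyReport:
    """Results for every group plus the across-group summary table."""

    results: dict[str, BistabilityResults]
    summary: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write per-group JSON/TSV reports and the summary TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, res in self.results.items():
            report = res.to_report()
            with open(out_dir / f"{label}.report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            flat = {
                k: v
                for k, v in report.items()
                if not isinstance(v, dict)
            }
            flat.update({f"landau_{k}": v for k, v in report["landau"].items()})
            flat.update({f"mixture_{k}": v for k, v in report["mixture"].items()})
            pd.DataFrame([flat]).to_csv(
                out_dir / f"{label}.report.tsv", sep="\t", index=False,
                float_format="%.17g",
            )
            proj = pd.DataFrame(
                {
                    "sample_id": list(report["projected"]),
                    "projection": list(report["projected"].values()),
                }
            )
            proj.to_csv(
                out_dir / f"{label}.projected.tsv", sep="\t", index=False,
                float_format="%.17g",
            )
            res.relevance().to_csv(
                out_dir / f"{label}.relevance.tsv", sep="\t", index=False,
                float_format="%.17g",
            )
        self.summary.to_csv(
            out_dir / "summary.tsv", sep="\t", index=False, float_format="%.17g"
        )


def _load_group(path: str | Path, label: str, manifest: StudyManifest) -> ExpressionGroup:
    df = read_expression(path)
    if manifest.housekeeping_gene_ids:
        df = geometric_mean_normalize(df, manifest.housekeeping_gene_ids)
    return ExpressionGroup.from_dataframe(
        df, group_label=label, value_scale=manifest.value_scale
    )


def _summarize(results: dict[str, BistabilityResults]) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        rows.append(
            {
                "group": label,
                "n_samples": res.n_samples,
                "sd_pc1": res.sd_pc1,
                "lambda1": res.axis.lambda1,
                "landau_c": res.landau.c,
                "landau_d": res.landau.d,
                "delta_bic_landau": res.delta_bic_landau,
                "delta_bic_mixture": res.delta_bic_mixture,
                "verdict_landau": res.comparison.verdict_landau,
                "verdict_mixture": res.comparison.verdict_mixture,
            }
        )
    return pd.DataFrame(rows)


def _fit_group(group: ExpressionGroup, manifest: StudyManifest) -> BistabilityResults:
    res = BistabilityModel(group).fit(
        threshold=manifest.threshold,
        d_min=manifest.d_min,
        orient_gene=manifest.reference_gene_for_orientation,
    )
    logger.info(
        "group %s: n=%d lambda1=%.4g dBIC_landau=%.3f dBIC_mixture=%.3f",
        group.group_label,
        res.n_samples,
        res.axis.lambda1,
        res.delta_bic_landau,
        res.delta_bic_mixture,
    )
    if res.n_samples < 10:
        logger.warning("group %s: only %d samples", group.group_label, res.n_samples)
    if res.landau.d <= manifest.d_min * (1 + 1e-9):
        logger.warning("group %s: quartic coefficient at its floor", group.group_label)
    return res


def run_study(manifest: StudyManifest) -> StudyReport:
    """Run the per-group analysis over every group in the manifest.

    All groups must share an identical gene panel; a mismatch raises with
    the symmetric difference of gene sets.
    """
    groups: dict[str, ExpressionGroup] = {}
    ref_genes: list[str] | None = None
    for label, path in manifest.groups:
        grp = _load_group(path, label, manifest)
        if ref_genes is None:
            ref_genes = grp.gene_ids
        elif set(grp.gene_ids) != set(ref_genes):
            diff = sorted(set(grp.gene_ids) ^ set(ref_genes))
            raise ValueError(
                f"group {label!r} gene set differs from the first group's; "
                f"symmetric difference: {diff}"
            )
        groups[label] = grp
    results = {label: _fit_group(grp, manifest) for label, grp in groups.items()}
    return StudyReport(results=results, summary=_summarize(results))


def pooled_case_control_run(
    control: ExpressionGroup,
    cases: list[ExpressionGroup],
    threshold: float = BIC_THRESHOLD,
    d_min: float = D_MIN,
) -> StudyReport:
    """Pool the control group with each case group and test for bimodality.

    For each case group (e.g. a disease stage), control and case samples
    are concatenated into one group and the standard fit is run; the
    projected coordinates keep a ground-truth origin label per sample.
    """
    if control.n_samples == 0:
        raise ValueError("control group is empty")
    results: dict[str, BistabilityResults] = {}
    for case in cases:
        if set(case.gene_ids) != set(control.gene_ids):
            diff = sorted(set(case.gene_ids) ^ set(control.gene_ids))
            raise ValueError(
                f"case group {case.group_label!r} gene set differs from "
                f"control; symmetric difference: {diff}"
            )
        case_df = case.to_dataframe()[control.gene_ids]
        pooled_values = np.vstack([control.values, case_df.to_numpy()])
        pooled = ExpressionGroup(
            values=pooled_values,
            gene_ids=list(control.gene_ids),
            sample_ids=(
                [f"control:{s}" for s in control.sample_ids]
                + [f"case:{s}" for s in case.sample_ids]
            ),
            group_label=case.group_label,
        )
        manifest = StudyManifest(
            groups=[(case.group_label, "<memory>")],
            threshold=threshold,
            d_min=d_min,
        )
        results[case.group_label] = _fit_group(pooled, manifest)
    return StudyReport(results=results, summary=_summarize(results))
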