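"""Orchestration of the full measurement-scheme x size-treatment grid.

One call runs every configured measurement scheme (linear protocols and the
full landmark configuration) through the three size treatments:

    raw            distances / partial-Procrustes coordinates (form)
    isometry_free  log-shape ratios / full-Procrustes shape
    allometry_free residuals of the allometric regression

and, per cell, fits a PCA, truncates at the cumulative-variance threshold,
computes leave-one-out LDA posteriors with equal priors and summarizes them
with the membership-based performance measures. Unidentified specimens are
classified from each scheme's isometry-free cell. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import AllometryFit, allometry_free, fit_allometry
from .discriminate import (
    ClassificationReport,
    LDAModel,
    classify_unknowns,
    fit_lda,
    loocv_memberships,
    ucpm,
)
from .features import GMM_SOURCE, FeatureTable, extract_distances, gmm_feature_table, log_shape_ratios
from .io import (
    LandmarkDataset,
    MeasurementProtocol,
    attach_groups,
    read_landmarks,
    read_metadata,
    read_protocol,
)
from .ordination import PCAModel, pca, project, retain_for_threshold
from .procrustes import align_new_to_consensus, gpa

logger = logging.getLogger("morphodisc")

TREATMENT_ORDER = ("raw", "isometry_free", "allometry_free")

__all__ = ["RunConfig", "CellResult", "GridResult", "run_pipeline", "run_grid", "report_table"]


@dataclass
class RunConfig:
    """Configuration of a full grid run (YAML-loadable)."""

    dataset: str
    format: str = "table"
    metadata: str | None = None
    protocols: dict[str, str] = field(default_factory=dict)
    include_gmm: bool = True
    treatments: tuple[str, ...] = TREATMENT_ORDER
    pca_threshold: float = 0.95
    n_perm: int = 1000
    priors: dict[str, float] | None = None
    seed: int = 0
    output: str = "morphodisc_out"

    def __post_init__(self) -> None:
        if not 0 < self.pca_threshold <= 1:
            raise ValueError("pca_threshold must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not self.protocols and not self.include_gmm:
            raise ValueError("at least one linear protocol or the GMM scheme must be enabled")
        bad = set(self.treatments) - set(TREATMENT_ORDER)
        if bad:
            raise ValueError(f"unknown treatments: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "treatments" in data:
            data["treatments"] = tuple(data["treatments"])
        return cls(**data)


@dataclass
class CellResult:
    source: str
    treatment: str
    pca_model: PCAModel
    n_retained: int
    scores: np.ndarray  # retained PC scores
    lda_model: LDAModel
    report: ClassificationReport


@dataclass
class GridResult:
    cells: dict[tuple[str, str], CellResult]
    allometry: dict[str, AllometryFit]
    unknown_predictions: dict[str, pd.DataFrame]
    failures: dict[tuple[str, str], str]
    classes: list[str]
    seed: int

    def report_table(self) -> pd.DataFrame:
        return report_table(self)


def _scheme_tables(
    scheme: str,
    dataset: LandmarkDataset,
    protocol: MeasurementProtocol | None,
    unknowns: LandmarkDataset | None,
) -> tuple[dict[str, FeatureTable], FeatureTable | None]:
    """Raw and isometry-free tables for one scheme, plus unknown iso table."""
    if scheme == GMM_SOURCE:
        partial = gpa(dataset, scale=False)
        full = gpa(dataset, scale=True)
        tables = {"raw": gmm_feature_table(partial), "isometry_free": gmm_feature_table(full)}
        unk = None
        if unknowns is not None:
            unk = gmm_feature_table(align_new_to_consensus(unknowns, full))
        return tables, unk
    assert protocol is not None
    raw = extract_distances(dataset, protocol)
    tables = {"raw": raw, "isometry_free": log_shape_ratios(raw)}
    unk = None
    if unknowns is not None:
        unk = log_shape_ratios(extract_distances(unknowns, protocol))
    return tables, unk


def run_pipeline(
    dataset: LandmarkDataset,
    protocols: dict[str, MeasurementProtocol] | None = None,
    include_gmm: bool = True,
    treatments: tuple[str, ...] = TREATMENT_ORDER,
    pca_threshold: float = 0.95,
    n_perm: int = 1000,
    priors: dict[str, float] | None = None,
    seed: int = 0,
) -> GridResult:
    """Run the full scheme x treatment grid on an in-memory dataset.

    Specimens labelled ``unknown`` are held out of every fit and classified
    from each scheme's isometry-free cell. A failing stage aborts only its
    own grid cell; the failure reason is recorded in ``failures``.
    """
    protocols = protocols or {}
    identified, unknowns = dataset.split_unknowns()
    classes = identified.known_group_labels()
    logger.info(
        "pipeline: %d identified specimens (%d groups), %d unknown, %d landmarks",
        identified.n_specimens, len(classes),
        0 if unknowns is None else unknowns.n_specimens, dataset.n_landmarks,
    )
    schemes: list[tuple[str, MeasurementProtocol | None]] = [
        (name, proto) for name, proto in protocols.items()
    ]
    if include_gmm:
        schemes.append((GMM_SOURCE, None))

    cells: dict[tuple[str, str], CellResult] = {}
    fits: dict[str, AllometryFit] = {}
    unknown_predictions: dict[str, pd.DataFrame] = {}
    failures: dict[tuple[str, str], str] = {}

    for scheme, proto in schemes:
        try:
            tables, unknown_iso = _scheme_tables(scheme, identified, proto, unknowns)
        except Exception as exc:  # noqa: BLE001 - isolate scheme failures
            logger.error("scheme %s: table construction failed: %s", scheme, exc)
            for t in treatments:
                failures[(scheme, t)] = str(exc)
            continue

        try:
            fit = fit_allometry(tables["isometry_free"], n_perm=n_perm, seed=seed)
            fits[scheme] = fit
            logger.info(
                "scheme %s: allometry R2=%.4f F=%.3f p=%.4g",
                scheme, fit.r_squared, fit.f_statistic, fit.p_value,
            )
            tables["allometry_free"] = allometry_free(fit)
        except Exception as exc:  # noqa: BLE001
            logger.error("scheme %s: allometric regression failed: %s", scheme, exc)
            if "allometry_free" in treatments:
                failures[(scheme, "allometry_free")] = str(exc)

        for treatment in treatments:
            table = tables.get(treatment)
            if table is None:
                continue
            try:
                cell = _run_cell(table, pca_threshold, priors)
            except Exception as exc:  # noqa: BLE001
                logger.error("cell %s/%s failed: %s", scheme, treatment, exc)
                failures[(scheme, treatment)] = str(exc)
                continue
            cells[(scheme, treatment)] = cell
            logger.info(
                "cell %s/%s: %d PCs retained, CR=%.3f AC=%.3f AS=%.3f CF=%.3f",
                scheme, treatment, cell.n_retained,
                cell.report.correctness_rate, cell.report.accuracy,
                cell.report.ability_to_separate, cell.report.confidence,
            )

        iso_cell = cells.get((scheme, "isometry_free"))
        if unknown_iso is not None and iso_cell is not None:
            labels, post = classify_unknowns(
                iso_cell.pca_model, iso_cell.lda_model, unknown_iso, iso_cell.n_retained
            )
            df = pd.DataFrame(post, columns=iso_cell.lda_model.classes,
                              index=unknown_iso.specimen_ids)
            df.insert(0, "predicted", labels)
            unknown_predictions[scheme] = df

    return GridResult(
        cells=cells,
        allometry=fits,
        unknown_predictions=unknown_predictions,
        failures=failures,
        classes=classes,
        seed=seed,
    )


def _run_cell(
    table: FeatureTable, pca_threshold: float, priors: dict[str, float] | None
) -> CellResult:
    model = pca(table)
    k = retain_for_threshold(model, pca_threshold)
    scores = model.scores[:, :k]
    lda = fit_lda(scores, table.groups, priors)
    memberships = loocv_memberships(scores, table.groups, priors)
    report = ucpm(memberships, table.groups, classes=lda.classes)
    return CellResult(
        source=table.source,
        treatment=table.treatment,
        pca_model=model,
        n_retained=k,
        scores=scores,
        lda_model=lda,
        report=report,
    )


def report_table(result: GridResult) -> pd.DataFrame:
    """Aggregate one row per successful grid cell (scheme x treatment).

    Columns: the four membership measures, per-class confidence, the scheme's
    allometric regression statistics, the retained-PC count and the PC1
    variance fraction. Row and column order are stable across runs.
    """
    rows = []
    schemes = list(dict.fromkeys(s for s, _ in result.cells))
    for scheme in schemes:
        for treatment in TREATMENT_ORDER:
            cell = result.cells.get((scheme, treatment))
            if cell is None:
                continue
            row: dict[str, object] = {"scheme": scheme, "treatment": treatment}
            row.update(cell.report.as_dict())
            fit = result.allometry.get(scheme)
            row["allometry_R2"] = fit.r_squared if fit else float("nan")
            row["allometry_F"] = fit.f_statistic if fit else float("nan")
            row["allometry_p"] = fit.p_value if fit else float("nan")
            row["n_retained_95"] = cell.n_retained
            row["PC1_fraction"] = float(cell.pca_model.variance_fractions[0])
            rows.append(row)
    if not rows:
        cols = ["scheme", "treatment", "CR", "AC", "AS", "CF",
                "allometry_R2", "allometry_F", "allometry_p",
                "n_retained_95", "PC1_fraction"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def run_grid(config: RunConfig) -> GridResult:
    """Load inputs per ``config``, run the grid and write the result bundle.

    Outputs under ``config.output``: ``performance_table.csv`` (one row per
    cell), per-cell PC score CSVs, LD1/LD2 score CSVs with 95% normal-ellipse
    parameters, unknown-specimen predictions and a JSON run manifest.
    """
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    dataset = read_landmarks(config.dataset, config.format)
    if config.metadata:
        dataset = attach_groups(dataset, read_metadata(config.metadata))
    protocols = {
        name: read_protocol(path, name=name) for name, path in config.protocols.items()
    }
    result = run_pipeline(
        dataset,
        protocols=protocols,
        include_gmm=config.include_gmm,
        treatments=tuple(config.treatments),
        pca_threshold=config.pca_threshold,
        n_perm=config.n_perm,
        priors=config.priors,
        seed=config.seed,
    )

    table = report_table(result)
    table.to_csv(out / "performance_table.csv", index=False, float_format="%.12g")

    for (scheme, treatment), cell in result.cells.items():
        stem = f"{scheme}_{treatment}".replace(" ", "_")
        pd.DataFrame(
            cell.scores,
            index=result.cells[(scheme, treatment)].report.true_labels,
            columns=[f"PC{i + 1}" for i in range(cell.scores.shape[1])],
        ).to_csv(out / f"scores_{stem}.csv", index_label="group", float_format="%.12g")
        _write_ld_outputs(cell, out / f"ld_{stem}.csv", out / f"ellipses_{stem}.csv")

    for scheme, df in result.unknown_predictions.items():
        df.to_csv(out / f"unknown_predictions_{scheme}.csv", index_label="specimen",
                  float_format="%.12g")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "pca_threshold": config.pca_threshold,
        "n_perm": config.n_perm,
        "schemes": sorted({s for s, _ in result.cells}),
        "n_cells": len(result.cells),
        "failures": {f"{s}/{t}": msg for (s, t), msg in result.failures.items()},
        "classes": result.classes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _write_ld_outputs(cell: CellResult, ld_path: Path, ellipse_path: Path) -> None:
    n_axes = min(2, cell.lda_model.scalings.shape[1])
    axes = cell.lda_model.scalings[:, :n_axes]
    ld = (cell.scores - cell.scores.mean(axis=0)) @ axes
    cols = [f"LD{i + 1}" for i in range(n_axes)]
    df = pd.DataFrame(ld, columns=cols)
    df.insert(0, "group", cell.report.true_labels)
    df.to_csv(ld_path, index=False, float_format="%.12g")

    if n_axes == 2:
        # 95% normal ellipse per group: mean, covariance axes, chi2(2) radius
        rows = []
        radius = float(np.sqrt(5.991464547107979))  # chi2.ppf(0.95, df=2)
        for cls in cell.lda_model.classes:
            mask = np.array(cell.report.true_labels) == cls
            if mask.sum() < 3:
                continue
            sub = ld[mask]
            mean = sub.mean(axis=0)
            cov = np.cov(sub.T)
            eigval, eigvec = np.linalg.eigh(cov)
            angle = float(np.degrees(np.arctan2(eigvec[1, 1], eigvec[0, 1])))
            rows.append(
                {
                    "group": cls,
                    "mean_LD1": mean[0],
                    "mean_LD2": mean[1],
                    "semi_major": radius * float(np.sqrt(eigval[1])),
                    "semi_minor": radius * float(np.sqrt(max(eigval[0], 0.0))),
                    "angle_deg": angle,
                }
            )
        pd.DataFrame(rows).to_csv(ellipse_path, index=False, float_format="%.12g")
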