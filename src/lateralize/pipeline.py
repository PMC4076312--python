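"""End-to-end orchestration: cohort -> mixture fits -> typing -> association.

A run takes a cohort (synthesized, read from a table, or built by computing
bootstrap laterality indices from a manifest of t-map files), fits Gaussian
mixtures per handedness group and pooled, assigns lateralization types, and
computes the association block (concordance kappa, Fisher tests, Spearman
correlation, occurrence regression).  Every stochastic stage is seeded and
the seeds are echoed into the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    cohen_kappa,
    collapse_dominance,
    contingency,
    fisher_exact,
    mps3,
    mps7,
    occurrence_regression,
    spearman,
)
from .bootstrap_li import BootstrapConfig, compute_hfli, load_volume
from .classify import (
    REFERENCE_THRESHOLDS,
    assign_types,
    derive_thresholds,
    find_local_minima,
    type_summary,
)
from .mixture_fit import EMSettings, select_model
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("lateralize")

__all__ = ["RunConfig", "RunReport", "run", "read_cohort", "write_report"]

REQUIRED_COLUMNS = ("subject_id", "handedness")


@dataclass
class RunConfig:
    """One analysis run.  Exactly one input mode must be set."""

    mode: str = "synthetic"  # "synthetic" | "cohort" | "tmaps"
    cohort_path: str | None = None
    manifest_path: str | None = None
    synth: CohortConfig = field(default_factory=CohortConfig)
    n_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    typing_preset: str = "reference"  # "reference" (cutpoints -50/18) | "derived"
    em: EMSettings = field(default_factory=EMSettings)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "cohort", "tmaps"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "cohort" and not self.cohort_path:
            raise ValueError("cohort mode needs cohort_path")
        if self.mode == "tmaps" and not self.manifest_path:
            raise ValueError("tmaps mode needs manifest_path")
        if self.typing_preset not in ("reference", "derived"):
            raise ValueError("typing_preset must be 'reference' or 'derived'")


@dataclass
class RunReport:
    """Structured result of one run; JSON-serializable via to_dict()."""

    config_echo: dict
    cohort: pd.DataFrame
    selection_tables: dict
    thresholds: dict
    type_summary: pd.DataFrame
    contingency_tables: dict
    statistics: dict
    issues: list

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "config": self.config_echo,
            "selection": {
                g: t.to_dataframe().to_dict(orient="records")
                for g, t in self.selection_tables.items()
            },
            "thresholds": self.thresholds,
            "type_summary": self.type_summary.to_dict(orient="records"),
            "contingency": {
                k: {
                    "rows": list(v.row_labels),
                    "cols": list(v.col_labels),
                    "counts": v.counts.tolist(),
                }
                for k, v in self.contingency_tables.items()
            },
            "statistics": self.statistics,
            "issues": self.issues,
        }


# ---------------------------------------------------------------------------
# Cohort input
# ---------------------------------------------------------------------------


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a tabular cohort file (TSV/CSV with header row).

    Malformed rows (handedness outside {RH, LH}, scores outside [-100, 100])
    are rejected with their line numbers; duplicate subject ids are an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")

    errors = []
    lineno = df.index + 2  # header is line 1
    bad_hand = ~df["handedness"].astype(str).isin(["RH", "LH"])
    for ln in lineno[bad_hand]:
        errors.append(f"line {ln}: handedness must be RH or LH")
    for col in ("mps", "hfli"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            out = vals.notna() & ((vals < -100) | (vals > 100))
            for ln in lineno[out]:
                errors.append(f"line {ln}: {col} outside [-100, 100]")
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate subject ids: {dupes}")
    if errors:
        raise ValueError("invalid cohort rows:\n" + "\n".join(errors))
    return df


def _cohort_from_manifest(manifest_path: str, bs: BootstrapConfig) -> pd.DataFrame:
    """Manifest: TSV with subject_id, handedness, [mps,] tmap, left_mask,
    right_mask[, exclusion]; laterality indices are computed per row."""
    man = read_cohort(manifest_path)
    base = Path(manifest_path).parent
    rows = []
    for _, rec in man.iterrows():
        vol = load_volume(
            base / rec["tmap"],
            base / rec["left_mask"],
            base / rec["right_mask"],
            base / rec["exclusion"] if "exclusion" in rec and pd.notna(rec["exclusion"]) else None,
        )
        res = compute_hfli(vol, bs)
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "handedness": rec["handedness"],
                "mps": rec.get("mps", np.nan),
                "hfli": res.hfli if res.valid else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


def run(config: RunConfig) -> RunReport:
    issues: list[str] = []

    if config.mode == "synthetic":
        cohort = generate_cohort(config.synth)
    elif config.mode == "cohort":
        cohort = read_cohort(config.cohort_path)
        if "hfli" not in cohort.columns:
            raise ValueError(
                "cohort file has no hfli column; use tmaps mode to compute it"
            )
    else:
        cohort = _cohort_from_manifest(config.manifest_path, config.bootstrap)
    cohort = cohort.copy()
    log.info("cohort: %d subjects (seed %d)", len(cohort), config.seed)

    # mixture fits per group and pooled
    groups = {
        "RH": cohort.loc[cohort["handedness"] == "RH", "hfli"].dropna().to_numpy(),
        "LH": cohort.loc[cohort["handedness"] == "LH", "hfli"].dropna().to_numpy(),
        "pooled": cohort["hfli"].dropna().to_numpy(),
    }
    selection: dict = {}
    for name, data in groups.items():
        if data.size == 0:
            issues.append(f"group {name}: no laterality indices, fit skipped")
            continue
        try:
            selection[name] = select_model(data, config.n_range, config.em)
            log.info(
                "group %s: best n=%d", name, selection[name].best_n
            )
        except (ValueError, RuntimeError) as exc:
            issues.append(f"group {name}: fit failed ({exc})")

    # typing thresholds; the preset path works even when no group could be
    # fit (tiny cohorts), derived thresholds genuinely need a fitted model
    thresholds_info: dict = {"preset": config.typing_preset}
    if config.typing_preset == "reference":
        thr = REFERENCE_THRESHOLDS
    else:
        if not selection:
            raise RuntimeError("derived thresholds need at least one fitted group")
        ref = selection.get("pooled") or next(iter(selection.values()))
        thr = derive_thresholds(ref.best_fit.model)
        if len(thr.cutpoints) != 2:
            issues.append(
                f"derived thresholds have {len(thr.cutpoints)} cutpoints, "
                "types beyond the standard three may be present"
            )
    thresholds_info["cutpoints"] = list(thr.cutpoints)
    thresholds_info["labels"] = list(thr.labels)
    for name, table in selection.items():
        thresholds_info[f"density_minima_{name}"] = [
            round(float(v), 3) for v in find_local_minima(table.best_fit.model)
        ]

    assignment = assign_types(cohort["hfli"], thr)
    cohort["lat_type"] = assignment.lat_type.values
    cohort["binary_type"] = assignment.binary_type.values
    if assignment.n_excluded:
        issues.append(f"{assignment.n_excluded} subjects lack an index; excluded")
    if "mps" in cohort.columns:
        has_mps = cohort["mps"].notna()
        cohort.loc[has_mps, "mps3"] = cohort.loc[has_mps, "mps"].map(mps3)
        cohort.loc[has_mps, "mps7"] = cohort.loc[has_mps, "mps"].map(mps7)

    summary = type_summary(cohort.dropna(subset=["hfli"]))

    # association block
    tables = {
        "type_by_handedness": contingency(
            cohort.dropna(subset=["hfli"]), "handedness", "lat_type"
        ),
        "dominance_2x2": collapse_dominance(cohort.dropna(subset=["hfli"])),
        "dominance_2x2_excl_sa": collapse_dominance(
            cohort.dropna(subset=["hfli"]), include_strongly_atypical=False
        ),
    }
    stats_block: dict = {"seed": config.seed}
    try:
        kappa = cohen_kappa(tables["dominance_2x2"])
        stats_block["kappa_dominance"] = {
            "kappa": kappa.kappa, "p": kappa.p,
            "observed": kappa.observed_agreement,
            "expected": kappa.expected_agreement,
        }
        kappa_ex = cohen_kappa(tables["dominance_2x2_excl_sa"])
        stats_block["kappa_dominance_excl_sa"] = {
            "kappa": kappa_ex.kappa, "p": kappa_ex.p,
        }
    except ValueError as exc:
        stats_block["kappa_dominance"] = {"kappa": np.nan, "p": np.nan}
        stats_block["kappa_dominance_excl_sa"] = {"kappa": np.nan, "p": np.nan}
        issues.append(f"dominance kappa undefined: {exc}")
    fisher = fisher_exact(tables["type_by_handedness"], seed=config.seed)
    stats_block["fisher_type_by_handedness"] = {
        "p": fisher.p, "method": fisher.method,
    }

    if "mps" in cohort.columns and cohort["mps"].notna().any():
        sub = cohort.dropna(subset=["hfli", "mps"])
        tables["type_by_mps3"] = contingency(sub, "mps3", "lat_type")
        rho = spearman(sub["mps"].to_numpy(), sub["hfli"].to_numpy())
        stats_block["spearman_mps_hfli"] = rho.estimate
        try:
            occ = occurrence_regression(sub)
            stats_block["occurrence_regression"] = occ.estimate
        except ValueError as exc:
            issues.append(f"occurrence regression skipped: {exc}")

    report = RunReport(
        config_echo={
            "mode": config.mode,
            "seed": config.seed,
            "n_range": list(config.n_range),
            "typing_preset": config.typing_preset,
            "em": vars(config.em).copy(),
        },
        cohort=cohort,
        selection_tables=selection,
        thresholds=thresholds_info,
        type_summary=summary,
        contingency_tables=tables,
        statistics=stats_block,
        issues=issues,
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: RunReport, directory: str | Path) -> dict:
    """Write the structured report (JSON) plus tabular mirrors (TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["report"] = directory / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_jsonable)
    paths["cohort"] = directory / "cohort.tsv"
    report.cohort.to_csv(paths["cohort"], sep="\t", index=False)
    for name, table in report.selection_tables.items():
        p = directory / f"model_selection_{name}.tsv"
        table.to_dataframe().to_csv(p, sep="\t", index=False)
        paths[f"selection_{name}"] = p
    paths["type_summary"] = directory / "type_summary.tsv"
    report.type_summary.to_csv(paths["type_summary"], sep="\t", index=False)
    for name, table in report.contingency_tables.items():
        p = directory / f"contingency_{name}.tsv"
        table.to_dataframe().to_csv(p, sep="\t")
        paths[f"contingency_{name}"] = p
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
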