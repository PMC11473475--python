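"""Repeat summaries, inter-system ratio tables and comparison reports.

Repeatability follows the source convention: the mean over repeated
acquisitions with the maximum half-dispersion (max - min)/2 as the error
estimator.  Ratio tables divide a reference system's mean CNRs by a
comparator's, cell by cell over (image kind, phantom half, iodine density),
and report the arithmetic mean of the full-precision cell ratios per image
kind, alongside a half-away-from-zero 1-decimal "printed" view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import tables
from .dosimetry import EU_MGD_LIMIT_55MM, check_dose_limit, he_dose_fraction, total_mgd
from .errors import ConfigurationError, PairingError
from .metrics import CNRMeasurement

CellKey = tuple[str, str, float]  # (image_kind, half, iodine_density)


def round_printed(value: float, ndigits: int = 1) -> float:
    """Half-away-from-zero rounding, matching printed-table presentation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RepeatSummary:
    mean: float
    half_dispersion: float
    n: int

    def __str__(self) -> str:  # "2.34 ± 0.03" style
        return f"{self.mean:.4g} ± {self.half_dispersion:.2g}"


def summarize_repeats(values: Sequence[float]) -> RepeatSummary:
    """Mean and maximum half-dispersion (max - min)/2 of repeated measurements."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty set of repeats")
    return RepeatSummary(
        mean=float(vals.mean()),
        half_dispersion=float((vals.max() - vals.min()) / 2.0),
        n=int(vals.size),
    )


@dataclass(frozen=True)
class RatioTable:
    reference_label: str
    comparator_label: str
    cells: dict  # CellKey -> reference/comparator ratio (full precision)
    mean_ratio: dict  # image_kind -> arithmetic mean of its cells

    def rounded(self, ndigits: int = 1) -> dict:
        """The 1-decimal presentation view of cells and means."""
        return {
            "cells": {k: round_printed(v, ndigits) for k, v in self.cells.items()},
            "mean_ratio": {k: round_printed(v, ndigits) for k, v in self.mean_ratio.items()},
        }


def cnr_ratio_table(
    reference: Mapping[CellKey, float],
    comparator: Mapping[CellKey, float],
    reference_label: str = "reference",
    comparator_label: str = "comparator",
) -> RatioTable:
    """Per-cell reference/comparator CNR ratios plus per-image-kind means."""
    missing = set(reference) - set(comparator)
    if missing:
        raise PairingError(f"comparator lacks keys: {sorted(missing)[:4]} ...")
    cells = {}
    for key, ref_val in reference.items():
        comp_val = comparator[key]
        if ref_val <= 0 or comp_val <= 0:
            raise PairingError(f"non-positive CNR at {key}")
        cells[key] = float(ref_val) / float(comp_val)
    mean_ratio = {}
    for kind in sorted({k[0] for k in cells}):
        vals = [v for k, v in cells.items() if k[0] == kind]
        mean_ratio[kind] = float(np.mean(vals))
    return RatioTable(reference_label, comparator_label, cells, mean_ratio)


def dose_increase_pct(reference_total: float, comparator_total: float) -> float:
    """100 * (comparator/reference - 1), percent."""
    if reference_total <= 0:
        raise ValueError("reference total dose must be positive")
    return 100.0 * (comparator_total / reference_total - 1.0)


# ---------------------------------------------------------------------------
# Measurement frames


MEASUREMENT_COLUMNS = [
    "study",
    "system",
    "aec_mode",
    "image_kind",
    "half",
    "iodine_density",
    "plug_id",
    "mpv_target",
    "mpv_bkg",
    "sd_bkg",
    "cnr",
    "residual_flag",
]


def measurements_to_frame(
    measurements: Iterable[CNRMeasurement], study: str, system: str, aec_mode: str
) -> pd.DataFrame:
    """Flatten CNR measurements into the canonical per-study table."""
    rows = [
        {
            "study": study,
            "system": system,
            "aec_mode": aec_mode,
            "image_kind": m.image_kind,
            "half": m.half,
            "iodine_density": m.iodine_density,
            "plug_id": m.plug_id,
            "mpv_target": m.stats.mpv_target,
            "mpv_bkg": m.stats.mpv_bkg,
            "sd_bkg": m.stats.sd_bkg,
            "cnr": m.cnr,
            "residual_flag": m.residual_flag,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def summarize_measurements(meas: pd.DataFrame) -> pd.DataFrame:
    """Repeat-summarize CNR per (system, aec_mode, image_kind, half, density)."""
    group_cols = ["system", "aec_mode", "image_kind", "half", "iodine_density", "residual_flag"]
    rows = []
    for key, grp in meas.groupby(group_cols, sort=True):
        summ = summarize_repeats(grp["cnr"].to_numpy())
        rows.append(dict(zip(group_cols, key)) | {
            "cnr_mean": summ.mean,
            "cnr_halfdisp": summ.half_dispersion,
            "n": summ.n,
        })
    return pd.DataFrame(rows)


def summary_to_cell_map(summary: pd.DataFrame) -> dict[CellKey, float]:
    """(image_kind, half, density) -> mean CNR for the iodine plugs."""
    sub = summary[~summary["residual_flag"]]
    return {
        (r.image_kind, r.half, float(r.iodine_density)): float(r.cnr_mean)
        for r in sub.itertuples()
    }


# ---------------------------------------------------------------------------
# Comparison report


@dataclass
class ComparisonReport:
    """Deterministic, serializable inter-system comparison.

    ``doses``, ``cnr``, ``residual`` and ``linearity`` are tidy DataFrames;
    ``ratios`` maps comparator label -> RatioTable.  Identical inputs
    produce byte-identical CSV/JSON output.
    """

    doses: pd.DataFrame
    cnr: pd.DataFrame
    residual: pd.DataFrame
    ratios: dict
    linearity: pd.DataFrame
    reference_label: str

    def to_json_dict(self) -> dict:
        ratios = {
            comp: {
                "cells": {f"{k[0]}|{k[1]}|{k[2]:g}": v for k, v in rt.cells.items()},
                "mean_ratio": rt.mean_ratio,
                "rounded_mean_ratio": rt.rounded()["mean_ratio"],
            }
            for comp, rt in sorted(self.ratios.items())
        }
        return {
            "reference": self.reference_label,
            "doses": self.doses.to_dict(orient="records"),
            "cnr": self.cnr.to_dict(orient="records"),
            "residual": self.residual.to_dict(orient="records"),
            "ratios": ratios,
            "linearity": self.linearity.to_dict(orient="records"),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.doses.to_csv(out / "doses.csv", index=False)
        self.cnr.to_csv(out / "cnr_summary.csv", index=False)
        self.residual.to_csv(out / "residual_cnr.csv", index=False)
        self.linearity.to_csv(out / "linearity.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary_text())

    def summary_text(self) -> str:
        lines = [f"CEM comparison report (reference: {self.reference_label})", ""]
        if not self.doses.empty:
            lines.append("Total MGD per system/AEC mode:")
            for r in self.doses.itertuples():
                verdict = "pass" if r.within_limit else "FAIL"
                lines.append(
                    f"  {r.label:>14s}: {r.total_mgy:5.2f} mGy"
                    f"  ({r.increase_vs_ref_pct:+.1f}% vs {self.reference_label},"
                    f" {EU_MGD_LIMIT_55MM} mGy limit: {verdict})"
                )
            lines.append("")
        for comp, rt in sorted(self.ratios.items()):
            means = ", ".join(
                f"{k}: {v:.2f} (printed view {round_printed(v):.1f})"
                for k, v in sorted(rt.mean_ratio.items())
            )
            lines.append(f"Mean CNR ratio {self.reference_label}/{comp}: {means}")
        return "\n".join(lines) + "\n"


def build_report(
    measurements: pd.DataFrame,
    doses: pd.DataFrame,
    reference_label: str = tables.REFERENCE_LABEL,
    dose_limit: float = EU_MGD_LIMIT_55MM,
) -> ComparisonReport:
    """Aggregate per-study measurement and dose tables into a report.

    ``measurements`` follows MEASUREMENT_COLUMNS (one row per plug, image
    kind and study).  ``doses`` needs columns study, system, aec_mode,
    energy, mgd_mgy (one row per image).  The label of each system/AEC mode
    is "system" or "system aec-suffix" matching the bundled table style.
    """
    from .metrics import signal_difference_linearity  # local import to avoid cycle at module load

    for frame_name, frame, cols in (
        ("measurements", measurements, {"system", "aec_mode", "image_kind", "cnr"}),
        ("doses", doses, {"system", "aec_mode", "energy", "mgd_mgy"}),
    ):
        if not frame.empty and not cols.issubset(frame.columns):
            raise ConfigurationError(f"{frame_name} table lacks columns {cols - set(frame.columns)}")

    def label_of(system: str, aec_mode: str) -> str:
        if not aec_mode or aec_mode in ("AOP/STD", "AutoFilter"):
            return system
        suffix = aec_mode.replace("dose level ", "")
        return f"{system} {suffix}"

    # --- dose section
    dose_rows = []
    if not doses.empty:
        per_image = (
            doses.groupby(["system", "aec_mode", "energy"])["mgd_mgy"]
            .apply(lambda v: summarize_repeats(v.to_numpy()).mean)
            .unstack("energy")
        )
        for (system, aec_mode), row in per_image.iterrows():
            le, he = float(row.get("LE", np.nan)), float(row.get("HE", np.nan))
            total = total_mgd(le, he)
            dose_rows.append(
                {
                    "label": label_of(system, aec_mode),
                    "mgd_le_mgy": le,
                    "mgd_he_mgy": he,
                    "total_mgy": total,
                    "he_fraction_pct": he_dose_fraction(le, he),
                    "within_limit": check_dose_limit(total, dose_limit),
                }
            )
    dose_df = pd.DataFrame(dose_rows)
    if not dose_df.empty:
        ref_rows = dose_df[dose_df["label"] == reference_label]
        ref_total = float(ref_rows["total_mgy"].iloc[0]) if len(ref_rows) else np.nan
        dose_df["increase_vs_ref_pct"] = [
            dose_increase_pct(ref_total, t) if np.isfinite(ref_total) else np.nan
            for t in dose_df["total_mgy"]
        ]
        dose_df = dose_df.sort_values("label").reset_index(drop=True)

    # --- CNR sections
    cnr_df = pd.DataFrame()
    residual_df = pd.DataFrame()
    ratios: dict = {}
    linearity_rows = []
    if not measurements.empty:
        summary = summarize_measurements(measurements)
        summary["label"] = [label_of(s, a) for s, a in zip(summary["system"], summary["aec_mode"])]
        residual_df = summary[summary["residual_flag"]].reset_index(drop=True)
        cnr_df = summary[~summary["residual_flag"]].reset_index(drop=True)
        by_label = {
            lbl: summary_to_cell_map(grp) for lbl, grp in summary.groupby("label", sort=True)
        }
        if reference_label in by_label and len(by_label) > 1:
            for comp, cell_map in by_label.items():
                if comp == reference_label:
                    continue
                ratios[comp] = cnr_ratio_table(
                    by_label[reference_label], cell_map, reference_label, comp
                )
        # linearity per label/half from per-study DES signal differences
        des = measurements[(measurements["image_kind"] == "DES") & (~measurements["residual_flag"])]
        for (system, aec_mode, half), grp in des.groupby(["system", "aec_mode", "half"], sort=True):
            mean_sd = grp.groupby("iodine_density")[["mpv_target", "mpv_bkg"]].mean()
            if len(mean_sd) < 3:
                continue
            x = mean_sd.index.to_numpy(dtype=float)
            y = (mean_sd["mpv_target"] - mean_sd["mpv_bkg"]).to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum((y - slope * x - intercept) ** 2)) / ss_tot
            linearity_rows.append(
                {
                    "label": label_of(system, aec_mode),
                    "half": half,
                    "slope": float(slope),
                    "intercept": float(intercept),
                    "r_squared": float(r2),
                }
            )
    return ComparisonReport(
        doses=dose_df,
        cnr=cnr_df,
        residual=residual_df,
        ratios=ratios,
        linearity=pd.DataFrame(linearity_rows),
        reference_label=reference_label,
    )


# ---------------------------------------------------------------------------
# Regeneration of the published derived quantities from the bundled tables


def regenerate_reference_tables(reference_label: str = tables.REFERENCE_LABEL) -> dict:
    """Recompute every derived quantity from the bundled printed tables.

    Returns ``{"dose_summary": DataFrame, "ratio_tables": {(kind, comparator):
    RatioTable}, "flags": DataFrame}``.  Cells whose recomputed-from-rounded
    value differs from the printed presentation are flagged (these are known
    rounding artifacts of the source, not corrected).
    """
    tf = tables.load_technical_factors()
    printed = tables.load_printed_dose_summary().set_index("label")
    rows = []
    flags = []
    per_label = tf.pivot_table(index="label", columns="energy", values="mgd_mean")
    ref_total = float(per_label.loc[reference_label].sum())
    for label in tables.LABELS:
        le, he = float(per_label.loc[label, "LE"]), float(per_label.loc[label, "HE"])
        total = total_mgd(le, he)
        inc = dose_increase_pct(ref_total, total)
        rows.append(
            {
                "label": label,
                "mgd_le_mgy": le,
                "mgd_he_mgy": he,
                "total_mgy": total,
                "he_fraction_pct": he_dose_fraction(le, he),
                "increase_vs_ref_pct": inc,
                "within_limit": check_dose_limit(total),
            }
        )
        if label in printed.index:
            pt = printed.loc[label, "printed_total_mgy"]
            if pd.notna(pt) and round_printed(total, 2) != float(pt):
                flags.append(
                    {
                        "quantity": f"total MGD {label}",
                        "recomputed": round_printed(total, 2),
                        "printed": float(pt),
                    }
                )
            pi = printed.loc[label, "printed_increase_pct"]
            if pd.notna(pi) and round_printed(inc, 1) != float(pi):
                flags.append(
                    {
                        "quantity": f"total increase vs {reference_label} {label}",
                        "recomputed": round_printed(inc, 1),
                        "printed": float(pi),
                    }
                )
    dose_summary = pd.DataFrame(rows)

    cnr_all = pd.concat([tables.load_cnr_raw(), tables.load_cnr_des()], ignore_index=True)
    cnr_ok = cnr_all[cnr_all["flag"] != "suspect"]
    printed_means = tables.load_printed_ratio_means()
    ratio_tables = {}
    for comparator in tables.LABELS:
        if comparator == reference_label:
            continue
        for kind in ("LE", "HE", "DES"):
            sub = cnr_ok[cnr_ok["image_kind"] == kind]
            ref_map = {
                (r.image_kind, r.half, float(r.iodine_mg_cm2)): float(r.cnr_mean)
                for r in sub[sub["label"] == reference_label].itertuples()
            }
            comp_map = {
                (r.image_kind, r.half, float(r.iodine_mg_cm2)): float(r.cnr_mean)
                for r in sub[sub["label"] == comparator].itertuples()
            }
            common = set(ref_map) & set(comp_map)
            rt = cnr_ratio_table(
                {k: ref_map[k] for k in common},
                {k: comp_map[k] for k in common},
                reference_label,
                comparator,
            )
            ratio_tables[(kind, comparator)] = rt
            pm = printed_means[
                (printed_means["image_kind"] == kind)
                & (printed_means["comparator"] == comparator)
            ]
            if len(pm):
                recomputed = round_printed(rt.mean_ratio[kind], 1)
                if recomputed != float(pm["printed_mean"].iloc[0]):
                    flags.append(
                        {
                            "quantity": f"mean {kind} ratio {reference_label}/{comparator}",
                            "recomputed": recomputed,
                            "printed": float(pm["printed_mean"].iloc[0]),
                        }
                    )
    return {
        "dose_summary": dose_summary,
        "ratio_tables": ratio_tables,
        "flags": pd.DataFrame(flags, columns=["quantity", "recomputed", "printed"]),
    }
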