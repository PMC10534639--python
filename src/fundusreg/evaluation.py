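"""FIRE-style registration-error evaluation.

A registration is scored by the mean Euclidean distance between each
ground-truth control point mapped from the source frame and its marked
position in the target frame. Over a batch of pairs, the success curve
gives the fraction of pairs registered below each error threshold from
0 to 25 px; its trapezoidal area normalised by 25 is the summary AUC.
Pairs whose estimation failed enter the curve as infinite error, so they
count against every threshold rather than being dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ControlPointSet, TransformModel

MAX_THRESHOLD = 25


@dataclass
class SuccessCurve:
    thresholds: np.ndarray
    rates: np.ndarray
    auc: float


def read_control_points(path) -> ControlPointSet:
    """Parse a whitespace-delimited control-point file.

    Each data row holds four numbers: x_src y_src x_tgt y_tgt. Lines
    starting with '#' and blank lines are ignored; a malformed row raises
    with its line number.
    """
    src, tgt = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                xs, ys, xt, yt = (float(f) for f in fields)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
            src.append((xs, ys))
            tgt.append((xt, yt))
    if not src:
        raise ValueError(f"{path}: no control points found")
    return ControlPointSet(src=np.asarray(src), tgt=np.asarray(tgt))


def write_control_points(cps: ControlPointSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# x_src y_src x_tgt y_tgt\n")
        for (xs, ys), (xt, yt) in zip(cps.src, cps.tgt):
            fh.write(f"{xs:.4f} {ys:.4f} {xt:.4f} {yt:.4f}\n")


def registration_error(model: TransformModel, cps: ControlPointSet) -> float:
    """Mean distance between mapped source control points and their
    target positions, in native pixels."""
    if len(cps) == 0:
        raise ValueError("empty control point set")
    mapped = model.apply(cps.src)
    return float(np.linalg.norm(mapped - cps.tgt, axis=1).mean())


def success_curve(errors, max_threshold: int = MAX_THRESHOLD) -> SuccessCurve:
    """Success rate at integer thresholds 0..max_threshold (inclusive <=)
    and normalised trapezoidal AUC. Failed registrations enter as +inf."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("errors must be nonempty")
    thresholds = np.arange(max_threshold + 1)
    with np.errstate(invalid="ignore"):
        rates = np.array([(errors <= t).mean() for t in thresholds])
    auc = float(np.trapezoid(rates, thresholds) / max_threshold)
    return SuccessCurve(thresholds=thresholds, rates=rates, auc=auc)


def evaluate_batch(results: list[dict], out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Summarise per-pair registration outcomes by category and overall.

    ``results`` holds dicts with keys ``pair_id``, ``error`` (px, may be
    inf for failures) and optionally ``category``; when absent, the
    category is the first letter of the pair id (S/P/A convention).
    Returns the per-pair table and a summary dict with per-category
    error statistics (over successful registrations at 25 px) and AUCs.
    Writes results.csv and summary.json when ``out_dir`` is given.
    """
    if not results:
        raise ValueError("no pairs to evaluate")
    rows = []
    for r in results:
        cat = r.get("category") or (str(r["pair_id"])[:1].upper() or "?")
        err = float(r["error"])
        rows.append(
            {
                "pair_id": r["pair_id"],
                "category": cat,
                "error_px": err,
                "success_25px": bool(err <= MAX_THRESHOLD),
            }
        )
    table = pd.DataFrame(rows)

    def _stats(errors: np.ndarray) -> dict:
        ok = errors[errors <= MAX_THRESHOLD]
        curve = success_curve(errors)
        out = {
            "n_pairs": int(errors.size),
            "successful_registrations": int(ok.size),
            "auc": curve.auc,
        }
        if ok.size:
            out.update(
                min_error=float(ok.min()),
                max_error=float(ok.max()),
                mean_error=float(ok.mean()),
                sd_error=float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
            )
        return out

    summary = {"overall": _stats(table["error_px"].to_numpy())}
    for cat, grp in table.groupby("category"):
        summary[str(cat)] = _stats(grp["error_px"].to_numpy())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "results.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return table, summary
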