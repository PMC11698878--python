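"""Assemble the study-style report: demographics chi-squares, per-arm
pre/post score comparisons, and the full cohort correlation matrix."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (
    CorrelationMatrix,
    chi_square_2x2,
    format_p,
    paired_t,
    pearson_matrix,
    two_sample_t,
)

__all__ = ["Report", "build_report", "CORRELATION_VARIABLES"]

_SCORE_COLS = [
    "subject", "group", "age", "sex", "education", "occupation",
    "moca_pre", "moca_post", "moca_gain", "mmse_pre", "mmse_post", "mmse_gain",
]
_PARAM_COLS = ["subject", "alpha", "beta", "gamma", "initial", "r_squared"]

#: Order of the correlation-matrix variables (trained arm only).
CORRELATION_VARIABLES = [
    "age",
    "moca_pre", "moca_post", "mmse_pre", "mmse_post",
    "moca_gain", "mmse_gain",
    "learning_amount", "learning_speed", "asymptote", "initial_performance",
]

_DEMOGRAPHICS = {
    "sex": ("male", "female"),
    "education": (">7y", "<=7y"),
    "occupation": ("mental", "manual"),
}


@dataclass(frozen=True)
class Report:
    demographics: pd.DataFrame
    scores: dict  # instrument -> comparison table
    correlations: CorrelationMatrix
    group_sizes: dict

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "demographics": self.demographics.to_dict(orient="records"),
            "scores": {k: v.to_dict(orient="records") for k, v in self.scores.items()},
            "correlations": {
                "variables": list(self.correlations.r.columns),
                "r": self.correlations.r.round(3).values.tolist(),
                "p": self.correlations.p.round(4).values.tolist(),
                "n": self.correlations.n,
            },
        }

    def write(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(name, df):
            path = out / name
            df.to_csv(path, index=False)
            written.append(path)

        _w("demographics.csv", self.demographics)
        for inst, table in self.scores.items():
            _w(f"scores_{inst}.csv", table)
        rpath = out / "correlation_r.csv"
        self.correlations.r.to_csv(rpath)
        written.append(rpath)
        ppath = out / "correlation_p.csv"
        self.correlations.p.to_csv(ppath)
        written.append(ppath)
        jpath = out / "report.json"
        jpath.write_text(json.dumps(self.to_dict(), indent=2))
        written.append(jpath)
        spath = out / "summary.txt"
        spath.write_text(self.summary_text())
        written.append(spath)
        return written

    def summary_text(self) -> str:
        lines = [
            "staircurve report",
            "=================",
            f"groups: training n={self.group_sizes['training']}, "
            f"control n={self.group_sizes['control']}",
            "",
            "Demographics (chi-square, df=1, no continuity correction):",
            self.demographics.to_string(index=False),
            "",
        ]
        for inst, table in self.scores.items():
            lines += [f"{inst.upper()} pre/post comparison:", table.to_string(index=False), ""]
        lines += [
            f"Correlation matrix (trained arm, n={self.correlations.n}); "
            "flags: * p<0.05, ** p<0.01",
            (self.correlations.r.round(3).astype(str) + self.correlations.flags).to_string(),
            "",
        ]
        return "\n".join(lines)


def _check_columns(df: pd.DataFrame, required, label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} table is missing columns: {missing}")


def _demographics_table(scores: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for item, cats in _DEMOGRAPHICS.items():
        counts = np.array(
            [
                [
                    int(((scores["group"] == g) & (scores[item] == c)).sum())
                    for c in cats
                ]
                for g in ("training", "control")
            ]
        )
        res = chi_square_2x2(counts)
        rows.append(
            {
                "item": item,
                "categories": f"{cats[0]}/{cats[1]}",
                "training": f"{counts[0, 0]}/{counts[0, 1]}",
                "control": f"{counts[1, 0]}/{counts[1, 1]}",
                "chi2": round(res.chi2, 3),
                "p": format_p(res.p),
            }
        )
    return pd.DataFrame(rows)


def _score_table(scores: pd.DataFrame, instrument: str, welch: bool) -> pd.DataFrame:
    pre, post, gain = (f"{instrument}_{s}" for s in ("pre", "post", "gain"))
    rows = []
    by_group = {}
    for g in ("training", "control"):
        sub = scores[scores["group"] == g]
        by_group[g] = sub
        t_res = paired_t(sub[pre], sub[post])
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "pre_mean": round(sub[pre].mean(), 2),
                "pre_sd": round(sub[pre].std(ddof=1), 2),
                "post_mean": round(sub[post].mean(), 2),
                "post_sd": round(sub[post].std(ddof=1), 2),
                "gain_mean": round(sub[gain].mean(), 2),
                "gain_sd": round(sub[gain].std(ddof=1), 2),
                "paired_t": round(t_res.t, 3),
                "paired_p": format_p(t_res.p),
            }
        )
    between = {"group": "between (t, p)", "n": ""}
    for phase, col in (("pre", pre), ("post", post), ("gain", gain)):
        res = two_sample_t(by_group["training"][col], by_group["control"][col], welch=welch)
        between[f"{phase}_mean"] = round(res.t, 3)
        between[f"{phase}_sd"] = format_p(res.p)
    rows.append(between)
    return pd.DataFrame(rows)


def build_report(
    scores: pd.DataFrame,
    params: pd.DataFrame,
    welch: bool = True,
) -> Report:
    """Build the four study-style tables plus the 11-variable correlation matrix.

    ``scores`` is the per-subject score table (both arms); ``params``
    the per-subject fitted learning-curve table (trained arm).  Every
    statistic in the output equals a direct call of the corresponding
    operation in :mod:`staircurve.stats` on the same data.
    """
    _check_columns(scores, _SCORE_COLS, "scores")
    _check_columns(params, _PARAM_COLS, "params")
    sizes = {
        g: int((scores["group"] == g).sum()) for g in ("training", "control")
    }
    for g, n in sizes.items():
        if n == 0:
            raise ValueError(f"{g} group is empty: report requires both arms")

    demo = _demographics_table(scores)
    score_tables = {
        inst: _score_table(scores, inst, welch) for inst in ("moca", "mmse")
    }

    joined = scores.merge(params, on="subject", how="inner")
    joined = joined[joined["group"] == "training"].rename(
        columns={
            "alpha": "learning_amount",
            "beta": "learning_speed",
            "gamma": "asymptote",
            "initial": "initial_performance",
        }
    )
    if len(joined) < 3:
        raise ValueError(
            "fewer than 3 trained subjects with fitted parameters: "
            "correlation matrix undefined"
        )
    corr = pearson_matrix(joined, CORRELATION_VARIABLES)
    return Report(
        demographics=demo, scores=score_tables, correlations=corr, group_sizes=sizes
    )
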