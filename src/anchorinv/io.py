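"""Reading and writing survey tables, configs and analysis reports.

The survey table is a plain CSV, one row per respondent, empty cell =
missing; the column dictionary is the one documented on
:mod:`anchorinv.dataset`.  Reports are serialized to JSON plus a plain-text
rendering shaped like a measurement-invariance summary table.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dataset import INDICATORS, SurveyDataset

_FIXED_COLS = {
    "resp_id",
    "group",
    "gender",
    "age_band",
    "education",
    "insurance",
    "vignette_set",
}
_SELF_RE = re.compile(r"^self_(\w+)$")
_VIG_RE = re.compile(r"^vig_(\w+)_L([1-5])$")


def read_survey(path: str | Path) -> SurveyDataset:
    """Read a survey CSV, validating the column dictionary and ratings."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col in _FIXED_COLS:
            continue
        m = _SELF_RE.match(col) or _VIG_RE.match(col)
        if not m or m.group(1) not in INDICATORS:
            raise ValueError(f"unknown column {col!r} in {path}")
    return SurveyDataset(df, meta={"source": str(path)})


def write_survey(data: SurveyDataset, path: str | Path) -> None:
    data.df.to_csv(path, index=False, na_rep="")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not k.startswith("_")
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_dict(report) -> dict:
    """JSON-ready dictionary for an AnalysisReport (estimates included,
    private optimizer state stripped)."""
    d = _jsonable(report)
    return d


def write_report(report, path: str | Path) -> None:
    """Write JSON (``<path>``) and a plain-text rendering (``<path>.txt``)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, default=str)
    with open(path.with_suffix(path.suffix + ".txt"), "w") as fh:
        fh.write(render_report(report))


def render_report(report) -> str:
    """Plain-text invariance summary in the familiar table layout."""
    lines = [f"workflow: {report.workflow}"]
    lines.append(
        "retained n: "
        + ", ".join(f"{g}={n}" for g, n in report.n_per_group.items())
    )
    hdr = (
        f"{'model':<22}{'chi2(df)':>16}{'dchi2(ddf)':>14}{'RMSEA':>8}"
        f"{'dRMSEA':>8}{'CFI':>8}{'dCFI':>8}{'aBIC':>10}  decision"
    )
    lines.append(hdr)
    for lv in report.invariance.levels:
        f = lv.fit
        dchi = (
            f"{lv.delta_chi2:.2f}({lv.delta_df})" if lv.delta_chi2 is not None else "-"
        )
        drm = f"{lv.delta_rmsea:+.3f}" if lv.delta_rmsea is not None else "-"
        dcf = f"{lv.delta_cfi:+.3f}" if lv.delta_cfi is not None else "-"
        lines.append(
            f"{lv.level:<22}{f.chi2:>10.2f}({f.df})"
            f"{dchi:>14}{f.rmsea:>8.3f}{drm:>8}{f.cfi:>8.3f}{dcf:>8}"
            f"{f.abic:>10.2f}  {lv.decision}"
        )
    if report.invariance.modifications:
        for mod in report.invariance.modifications:
            lines.append(
                f"  modification: error covariance {mod['added']} "
                f"(MI={mod['mi']:.2f}, EPC={mod['epc']:.3f})"
            )
    for key, val in report.diagnostics.items():
        if isinstance(val, float):
            lines.append(f"{key}: {val:.4f}")
        else:
            lines.append(f"{key}: {val}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------
def spec_to_yaml(spec, design, path: str | Path) -> None:
    """Serialize a PopulationSpec + VignetteDesign to one YAML file."""
    doc = {
        "population": _jsonable(spec),
        "design": {
            "sets": {
                int(k): {"indicators": list(v[0]), "levels": list(v[1])}
                for k, v in design.sets.items()
            },
            "assignment": {int(k): float(v) for k, v in design.assignment.items()},
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path: str | Path):
    from .synthetic import PopulationSpec, VignetteDesign

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pop = doc["population"]
    for key in ("loadings", "intercepts", "resid_sd", "gamma"):
        pop[key] = {g: np.asarray(v, float) for g, v in pop[key].items()}
    pop["theta"] = np.asarray(pop["theta"], float)
    pop["vignette_sd"] = np.asarray(pop["vignette_sd"], float)
    pop["groups"] = tuple(pop["groups"])
    pop["age_probs"] = tuple(pop["age_probs"])
    pop["edu_probs"] = tuple(pop["edu_probs"])
    spec = PopulationSpec(**pop)
    design = VignetteDesign(
        sets={
            int(k): (tuple(v["indicators"]), tuple(v["levels"]))
            for k, v in doc["design"]["sets"].items()
        },
        assignment={int(k): float(v) for k, v in doc["design"]["assignment"].items()},
    )
    return spec, design
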