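"""Serialization: YAML/JSON spec files, long-format CSV panels, stacks."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .panel import ComponentPanel, MissingnessMask
from .simgen import CohortSpec, MnarScenario, SurvivalSpec

SCHEMA_VERSION = 1


def save_cohort_spec(spec: CohortSpec, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "cohort_spec": _plain(asdict(spec))}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_cohort_spec(path) -> CohortSpec:
    raw = yaml.safe_load(Path(path).read_text())
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported spec schema version {raw.get('schema_version')!r}")
    body = raw["cohort_spec"]
    body["variables"] = tuple(body["variables"])
    body["binary_variables"] = frozenset(body["binary_variables"])
    for key in ("means", "sds", "binary_targets"):
        body[key] = {k: tuple(v) for k, v in body[key].items()}
    spec = CohortSpec(**body)
    spec.validate()
    return spec


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_panel(panel: ComponentPanel, path, mask: MissingnessMask | None = None) -> None:
    panel.to_long(mask).to_csv(path, index=False)


def load_panel(path, **kwargs):
    return ComponentPanel.from_long(pd.read_csv(path), **kwargs)


def save_stack(stack, out_dir) -> None:
    """Directory of wide CSVs (imp_j{j}_k{k}.csv) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, block in enumerate(stack.panels, start=1):
        for k, panel in enumerate(block, start=1):
            frame = panel.data.join(panel.covariates)
            frame.to_csv(out / f"imp_j{j}_k{k}.csv", index_label="subject_id")
    manifest = {
        "m": stack.m,
        "n": stack.n,
        "k_cont": stack.assumption.k_cont,
        "k_bin": stack.assumption.k_bin,
        "structure": stack.config.structure,
        "cox_mode": stack.config.cox_mode,
        "n_iterations": stack.config.n_iterations,
        "seed": stack.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def save_criteria(criteria, path) -> None:
    """Ideal-level criteria in the same versioned YAML schema."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "criteria": {
            "metadata": _plain(criteria.metadata),
            "rules": [
                {"component": r.component, "terms": [list(t) for t in r.terms]}
                for r in criteria.rules
            ],
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_criteria(path):
    from .composite import ComponentRule, IdealCriteria

    raw = yaml.safe_load(Path(path).read_text())
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported spec schema version {raw.get('schema_version')!r}")
    body = raw["criteria"]
    rules = tuple(
        ComponentRule(r["component"], tuple((v, op, float(thr)) for v, op, thr in r["terms"]))
        for r in body["rules"]
    )
    return IdealCriteria(rules=rules, metadata=body.get("metadata", {}))


def pooled_results_frame(pooled: dict, stack=None) -> pd.DataFrame:
    """Flatten ``{parameter: PooledEstimate}`` for CSV export.

    Carries the stack's assumption and FCS structure when available.
    """
    rows = []
    for param, pe in pooled.items():
        row = {
            "parameter": param,
            "q_bar": pe.q_bar,
            "u_bar": pe.u_bar,
            "b": pe.b_between,
            "w": pe.w_within,
            "t": pe.t_total,
            "df": pe.df,
            "ci_low": pe.ci_low,
            "ci_high": pe.ci_high,
            "m": pe.m,
            "n": pe.n,
        }
        if stack is not None:
            row.update(
                k_cont=stack.assumption.k_cont,
                k_bin=stack.assumption.k_bin,
                fcs_structure=stack.config.structure,
            )
        rows.append(row)
    return pd.DataFrame(rows)
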