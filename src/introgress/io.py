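"""Config-file loading, fixture export, and tabular output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import yaml

from .config import Scenario, scenario_from_dict, scenario_to_dict
from .fixtures import get_fixture

__all__ = ["load_scenario", "save_scenario", "export_fixture", "write_results"]

PathLike = Union[str, Path]


def load_scenario(path: PathLike) -> Scenario:
    """Load and fully validate a scenario from a JSON or YAML config file.

    Every architecture/selection/recombination invariant is checked at load
    time; violations raise ValueError naming the offending class or value.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    text = p.read_text()
    if p.suffix in {".yaml", ".yml"}:
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {p} must contain a mapping at top level")
    return scenario_from_dict(cfg)


def save_scenario(scenario: Scenario, path: PathLike) -> Path:
    p = Path(path)
    if p.suffix in {".yaml", ".yml"}:
        p.write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))
    else:
        p.write_text(json.dumps(scenario_to_dict(scenario), indent=2) + "\n")
    return p


def export_fixture(name: str, path: PathLike) -> Path:
    """Write a named fixture's scenario as a config file.

    The fixture's description and sweep grid are embedded under ``meta`` so
    the provenance travels with the file.
    """
    fx = get_fixture(name)  # raises with the list of known names
    d = scenario_to_dict(fx.scenario)
    meta = dict(d.get("meta", {}))
    meta["description"] = fx.description
    if fx.sweep:
        meta["sweep"] = fx.sweep
    d["meta"] = meta
    p = Path(path)
    p.write_text(json.dumps(d, indent=2) + "\n")
    return p


def write_results(
    table: Sequence[Mapping[str, object]],
    path: PathLike,
    format: Optional[str] = None,
    columns: Optional[List[str]] = None,
    header_comment: Optional[str] = None,
) -> Path:
    """Write a list of row mappings as TSV (default) or JSON.

    Floats are written at full precision (repr); missing cells are empty.
    A ``header_comment`` (e.g. the seed used) is prefixed with '#'.
    """
    p = Path(path)
    fmt = format or ("json" if p.suffix == ".json" else "tsv")
    if fmt == "json":
        payload = {"rows": list(map(dict, table))}
        if header_comment:
            payload["comment"] = header_comment
        p.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return p
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    if columns is None:
        columns = []
        for row in table:
            for k in row:
                if k not in columns:
                    columns.append(k)
    lines = []
    if header_comment:
        lines.append("# " + header_comment)
    lines.append("\t".join(columns))
    for row in table:
        lines.append("\t".join(_cell(row.get(c)) for c in columns))
    p.write_text("\n".join(lines) + "\n")
    return p


def _cell(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)
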