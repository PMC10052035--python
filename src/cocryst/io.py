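"""CSV/JSON/YAML readers and writers, report rendering, run manifests.

All tables are comma-separated UTF-8 with a header row and "." decimal
separator; scientific notation is accepted.  Unit conversions (degrees
Celsius to kelvin, kcal/mol to kJ/mol) happen on read, so the in-memory
objects are always in kelvin and kJ/mol.  Validation errors name the
file, row and column they come from.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .evaluate import LabeledScore
from .mep import KCAL_TO_KJ, InteractionSite, MoleculeSites
from .qtaim import CriticalPoint
from .thermo import CELSIUS_OFFSET, CocrystalSystem, SolubilityRecord

__all__ = [
    "TableError",
    "read_sites",
    "write_sites",
    "read_solubility",
    "write_solubility",
    "read_eutectic",
    "write_eutectic",
    "read_predictions",
    "write_predictions",
    "read_critical_points",
    "write_critical_points",
    "read_system",
    "render_report",
    "RunManifest",
    "write_manifest",
]


class TableError(ValueError):
    """A table failed validation; message carries file/row/column context."""


def _fail(path, row, column, msg) -> None:
    raise TableError(f"{path}: row {row}, column {column!r}: {msg}")


def _load(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: file not found")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required columns {missing}")
    return df


def _temperature_to_k(value: float, unit: str, path, row) -> float:
    unit = str(unit).strip()
    if unit in ("K", "k"):
        return float(value)
    if unit in ("C", "c", "degC"):
        return float(value) + CELSIUS_OFFSET
    _fail(path, row, "temperature_unit", f"unknown unit {unit!r}")


# --- interaction-site tables -------------------------------------------------

def read_sites(path: str | Path) -> dict[str, MoleculeSites]:
    """Site table -> MoleculeSites per molecule_id.

    Columns: molecule_id, site_id, kind (donor|acceptor), esp_value,
    esp_unit (kJ/mol|kcal/mol).
    """
    df = _load(path, ["molecule_id", "site_id", "kind", "esp_value", "esp_unit"])
    molecules: dict[str, MoleculeSites] = {}
    for i, rec in df.iterrows():
        kind = str(rec["kind"]).strip()
        if kind not in ("donor", "acceptor"):
            _fail(path, i, "kind", f"expected donor|acceptor, got {kind!r}")
        unit = str(rec["esp_unit"]).strip()
        if unit == "kJ/mol":
            esp = float(rec["esp_value"])
        elif unit == "kcal/mol":
            esp = float(rec["esp_value"]) * KCAL_TO_KJ
        else:
            _fail(path, i, "esp_unit", f"unknown unit {unit!r}")
        mol_id = str(rec["molecule_id"])
        mol = molecules.setdefault(mol_id, MoleculeSites(mol_id, [], []))
        try:
            site = InteractionSite.from_esp(str(rec["site_id"]), kind, esp)
        except ValueError as err:
            _fail(path, i, "esp_value", str(err))
        (mol.donors if kind == "donor" else mol.acceptors).append(site)
    # re-validate ordering/duplicates once lists are complete
    return {
        mid: MoleculeSites(mid, m.donors, m.acceptors)
        for mid, m in molecules.items()
    }


def write_sites(molecules: Mapping[str, MoleculeSites], path: str | Path) -> None:
    rows = []
    for mol in molecules.values():
        for s in mol.donors + mol.acceptors:
            rows.append({
                "molecule_id": mol.molecule_id, "site_id": s.site_id,
                "kind": s.kind, "esp_value": repr(s.esp_value),
                "esp_unit": "kJ/mol",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# --- solubility & system tables ----------------------------------------------

def read_solubility(path: str | Path) -> list[SolubilityRecord]:
    """Columns: compound_id, solvent, temperature, temperature_unit (C|K),
    solubility_mol_per_L, sd (optional, blank allowed)."""
    df = _load(path, ["compound_id", "solvent", "temperature",
                      "temperature_unit", "solubility_mol_per_L"])
    records = []
    for i, rec in df.iterrows():
        T = _temperature_to_k(rec["temperature"], rec["temperature_unit"], path, i)
        sol = float(rec["solubility_mol_per_L"])
        if sol <= 0:
            _fail(path, i, "solubility_mol_per_L",
                  f"solubility must be positive, got {sol}")
        sd = rec.get("sd")
        sd = None if sd is None or pd.isna(sd) else float(sd)
        records.append(SolubilityRecord(
            compound_id=str(rec["compound_id"]), solvent=str(rec["solvent"]),
            temperature=T, solubility=sol, replicate_sd=sd,
        ))
    return records


def write_solubility(records: Sequence[SolubilityRecord], path: str | Path) -> None:
    pd.DataFrame([
        {"compound_id": r.compound_id, "solvent": r.solvent,
         "temperature": repr(r.temperature), "temperature_unit": "K",
         "solubility_mol_per_L": repr(r.solubility),
         "sd": "" if r.replicate_sd is None else repr(r.replicate_sd)}
        for r in records
    ]).to_csv(path, index=False)


def read_system(yaml_path: str | Path, solubility_csv: str | Path) -> CocrystalSystem:
    """Assemble a CocrystalSystem from a YAML descriptor + solubility CSV.

    The YAML names the components, stoichiometry and the per-temperature
    cocrystal-equilibrium concentrations; pure-component saturation
    concentrations at matching temperatures come from the CSV.
    """
    descriptor = yaml.safe_load(Path(yaml_path).read_text())
    api_id, cf_id = str(descriptor["api_id"]), str(descriptor["coformer_id"])
    stoich = tuple(int(v) for v in descriptor.get("stoichiometry", (1, 1)))
    unit = str(descriptor.get("temperature_unit", "K"))
    records = read_solubility(solubility_csv)
    pure: dict[float, tuple[float, float]] = {}
    by_T: dict[float, dict[str, float]] = {}
    for r in records:
        by_T.setdefault(round(r.temperature, 6), {})[r.compound_id] = r.solubility
    cocrystal: dict[float, tuple[float, float]] = {}
    for i, row in enumerate(descriptor["cocrystal_equilibrium"]):
        T = _temperature_to_k(row["temperature"], unit, yaml_path, i)
        key = round(T, 6)
        if key not in by_T or api_id not in by_T[key] or cf_id not in by_T[key]:
            raise TableError(
                f"{yaml_path}: row {i}: no pure-component solubility for both "
                f"{api_id!r} and {cf_id!r} at {T} K in {solubility_csv}"
            )
        pure[T] = (by_T[key][api_id], by_T[key][cf_id])
        cocrystal[T] = (float(row["a_cc_api"]), float(row["a_cc_coformer"]))
    return CocrystalSystem(api_id=api_id, coformer_id=cf_id,
                           stoichiometry=stoich, pure=pure, cocrystal=cocrystal)


# --- eutectic tables ---------------------------------------------------------

def read_eutectic(path: str | Path) -> list[dict[str, Any]]:
    """Columns: system_id, cbz_eu, cbz_eu_sd, cf_eu, cf_eu_sd, cf_intrinsic."""
    df = _load(path, ["system_id", "cbz_eu", "cf_eu"])
    rows = []
    for i, rec in df.iterrows():
        for col in ("cbz_eu", "cf_eu"):
            if float(rec[col]) <= 0:
                _fail(path, i, col, f"must be positive, got {rec[col]}")

        def opt(col):
            v = rec.get(col)
            return 0.0 if v is None or pd.isna(v) else float(v)

        rows.append({
            "system_id": str(rec["system_id"]),
            "cbz_eu": float(rec["cbz_eu"]), "cbz_eu_sd": opt("cbz_eu_sd"),
            "cf_eu": float(rec["cf_eu"]), "cf_eu_sd": opt("cf_eu_sd"),
            "cf_intrinsic": (None if "cf_intrinsic" not in df.columns
                             or pd.isna(rec["cf_intrinsic"])
                             else float(rec["cf_intrinsic"])),
        })
    return rows


def write_eutectic(rows: Sequence[Mapping[str, Any]], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


# --- prediction tables -------------------------------------------------------

def read_predictions(
    path: str | Path,
    orientations: Mapping[str, str] | None = None,
) -> dict[str, list[LabeledScore]]:
    """Columns: coformer_id, outcome (1|0), method, score.

    `orientations` maps method name to higher-is-positive (default) or
    lower-is-positive.
    """
    df = _load(path, ["coformer_id", "outcome", "method", "score"])
    orientations = orientations or {}
    datasets: dict[str, list[LabeledScore]] = {}
    for i, rec in df.iterrows():
        outcome = str(rec["outcome"]).strip()
        if outcome not in ("0", "1"):
            _fail(path, i, "outcome", f"expected 1|0, got {outcome!r}")
        method = str(rec["method"])
        datasets.setdefault(method, []).append(LabeledScore(
            coformer_id=str(rec["coformer_id"]),
            outcome=outcome == "1",
            score=float(rec["score"]),
            orientation=orientations.get(method, "higher-is-positive"),
        ))
    return datasets


def write_predictions(
    datasets: Mapping[str, Sequence[LabeledScore]], path: str | Path
) -> None:
    rows = []
    for method, data in datasets.items():
        for d in data:
            rows.append({"coformer_id": d.coformer_id,
                         "outcome": int(d.outcome), "method": method,
                         "score": repr(d.score)})
    pd.DataFrame(rows).to_csv(path, index=False)


# --- critical-point tables ---------------------------------------------------

def read_critical_points(path: str | Path) -> list[CriticalPoint]:
    """Columns: cp_id, cp_type, rho_b, laplacian, g_b, atom_a, atom_b,
    distance (optional)."""
    df = _load(path, ["cp_id", "cp_type", "rho_b", "laplacian", "g_b"])
    points = []
    for i, rec in df.iterrows():
        dist = rec.get("distance")
        try:
            points.append(CriticalPoint(
                cp_id=str(rec["cp_id"]), cp_type=str(rec["cp_type"]),
                rho_b=float(rec["rho_b"]), laplacian=float(rec["laplacian"]),
                g_b=float(rec["g_b"]),
                atom_pair=(str(rec.get("atom_a", "")), str(rec.get("atom_b", ""))),
                distance=None if dist is None or pd.isna(dist) else float(dist),
            ))
        except ValueError as err:
            _fail(path, i, "cp_type", str(err))
    return points


def write_critical_points(points: Sequence[CriticalPoint], path: str | Path) -> None:
    pd.DataFrame([
        {"cp_id": p.cp_id, "cp_type": p.cp_type, "rho_b": repr(p.rho_b),
         "laplacian": repr(p.laplacian), "g_b": repr(p.g_b),
         "atom_a": p.atom_pair[0], "atom_b": p.atom_pair[1],
         "distance": "" if p.distance is None else repr(p.distance)}
        for p in points
    ]).to_csv(path, index=False)


# --- report rendering --------------------------------------------------------

def _plain(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN -> null for JSON
        return None
    return obj


def render_report(
    rows: Sequence[Mapping[str, Any]],
    fmt: str = "json",
    columns: Sequence[str] | None = None,
) -> str:
    """Render result rows deterministically as json, csv or markdown.

    Column order is the given `columns` or the key order of the first
    row; rounding is the caller's responsibility.
    """
    rows = [_plain(r) for r in rows]
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    if fmt == "json":
        return json.dumps([{c: r.get(c) for c in columns} for r in rows],
                          indent=2, sort_keys=False) + "\n"
    if fmt == "csv":
        header = ",".join(columns)
        lines = [header] + [
            ",".join("" if r.get(c) is None else str(r.get(c)) for c in columns)
            for r in rows
        ]
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = ["| " + " | ".join(columns) + " |",
                 "|" + "|".join("---" for _ in columns) + "|"]
        for r in rows:
            lines.append("| " + " | ".join(
                "" if r.get(c) is None else str(r.get(c)) for c in columns) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format: {fmt!r}")


# --- run provenance ----------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    command: str
    seed: int | None
    timestamp: str
    version: str
    input_digests: dict[str, str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_path: str | Path,
    inputs: Sequence[str | Path] = (),
    seed: int | None = None,
    argv: Sequence[str] | None = None,
) -> RunManifest:
    """Write `<out>.manifest.json` recording command, seed and input digests."""
    out_path = Path(out_path)
    manifest = RunManifest(
        command=" ".join(argv if argv is not None else sys.argv),
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
        version=__version__,
        input_digests={str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    )
    Path(str(out_path) + ".manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
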