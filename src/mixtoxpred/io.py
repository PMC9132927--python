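"""Reading mixture templates and structures; writing the prediction report.

Template dialect
----------------
Delimited text (UTF-8, comma separator, dot decimal) with optional
``# key: value`` header lines for product metadata (``product_name``,
``output_unit``, ``endpoint_type``) and one row per component::

    name,cas,component_type,physical_state,composition_percent,
    molecular_weight,endpoint_type,endpoint_value,endpoint_unit,
    drc_model,drc_unit,alpha,beta,gamma,delta

Compositions are percent in the file and fractions inside the engine;
conversion happens only at this boundary.  The same columns are accepted
from a spreadsheet (first sheet; optional ``product`` sheet with key/value
metadata).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .drc import FittedDRC, get_model
from .mixture import MixtureComponent, MixtureSpec, PredictionResult, lowest_predicted_ecx
from .units import ConcentrationValue, normalize_unit

__all__ = [
    "TemplateError",
    "MANDATORY_COLUMNS",
    "TEMPLATE_COLUMNS",
    "read_mixture_table",
    "write_mixture_table",
    "read_structures",
    "attach_structures",
    "write_report",
]

MANDATORY_COLUMNS = ("name", "composition_percent")
TEMPLATE_COLUMNS = (
    "name", "cas", "component_type", "physical_state", "composition_percent",
    "molecular_weight", "endpoint_type", "endpoint_value", "endpoint_unit",
    "drc_model", "drc_unit", "alpha", "beta", "gamma", "delta",
)
_DRC_COLUMNS = ("drc_model", "drc_unit", "alpha", "beta")


class TemplateError(ValueError):
    """Row- or column-addressed template validation failure."""


def _is_blank(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and not v.strip()


def _read_meta_and_table(path: Path):
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
        meta = {}
        try:
            mdf = pd.read_excel(path, sheet_name="product", header=None)
            meta = {str(k).strip(): str(v).strip() for k, v in zip(mdf[0], mdf[1])}
        except (ValueError, KeyError):
            pass
        return meta, df
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("#").split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    return meta, df


def read_mixture_table(path: str | Path) -> tuple[MixtureSpec, list[str]]:
    """Parse and validate a mixture template.

    Returns the spec plus a list of per-row warnings (e.g. missing optional
    toxicity information, which limits which models can run).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, df = _read_meta_and_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TemplateError(f"missing mandatory column(s): {missing}")

    warnings_out: list[str] = []
    components: list[MixtureComponent] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        name = row.get("name")
        if _is_blank(name):
            raise TemplateError(f"row {rowno}: mandatory field 'name' is empty")
        name = str(name).strip()
        pct = row.get("composition_percent")
        if _is_blank(pct):
            raise TemplateError(f"row {rowno} ({name}): composition_percent is mandatory")
        pct = float(pct)
        if not 0 < pct <= 100:
            raise TemplateError(
                f"row {rowno} ({name}): composition_percent must be in (0, 100], got {pct}"
            )
        cas = None if _is_blank(row.get("cas")) else str(row.get("cas")).strip()
        mw = None if _is_blank(row.get("molecular_weight")) else float(row.get("molecular_weight"))

        endpoint = None
        if not _is_blank(row.get("endpoint_value")):
            if _is_blank(row.get("endpoint_unit")):
                raise TemplateError(
                    f"row {rowno} ({name}): endpoint_value requires endpoint_unit"
                )
            try:
                endpoint = ConcentrationValue(
                    float(row["endpoint_value"]), str(row["endpoint_unit"]).strip()
                )
            except ValueError as err:
                raise TemplateError(f"row {rowno} ({name}): {err}") from None

        drc_present = [c for c in _DRC_COLUMNS if c in df.columns and not _is_blank(row.get(c))]
        drc = None
        if drc_present:
            absent = [c for c in _DRC_COLUMNS if c not in drc_present]
            if absent:
                raise TemplateError(
                    f"row {rowno} ({name}): DRC fields must be all-present or all-absent; "
                    f"missing {absent}"
                )
            model_id = str(row["drc_model"]).strip()
            try:
                model = get_model(model_id)
            except KeyError as err:
                raise TemplateError(f"row {rowno} ({name}): {err.args[0]}") from None
            params = [float(row["alpha"]), float(row["beta"])]
            for extra in ("gamma", "delta")[: model.n_params - 2]:
                if _is_blank(row.get(extra)):
                    raise TemplateError(
                        f"row {rowno} ({name}): model {model_id} requires parameter {extra}"
                    )
                params.append(float(row[extra]))
            try:
                drc = FittedDRC(model_id, tuple(params), str(row["drc_unit"]).strip())
            except ValueError as err:
                raise TemplateError(f"row {rowno} ({name}): {err}") from None
        if endpoint is None and drc is None:
            warnings_out.append(
                f"row {rowno} ({name}): no toxicity information; only models that "
                "do not need it will be available"
            )
        elif drc is None:
            warnings_out.append(
                f"row {rowno} ({name}): endpoint value only (no DRC); curve-based "
                "models unavailable for this mixture"
            )
        components.append(MixtureComponent(
            name=name, cas=cas, fraction=pct / 100.0, mw=mw,
            endpoint_value=endpoint, drc=drc,
        ))

    spec = MixtureSpec(
        components=tuple(components),
        output_unit=normalize_unit(meta.get("output_unit", "uM")),
        endpoint_type=meta.get("endpoint_type", "EC50"),
        product_name=meta.get("product_name", path.stem),
    )
    return spec, warnings_out


def write_mixture_table(spec: MixtureSpec, path: str | Path) -> Path:
    """Serialize a spec back to the template dialect (CSV roundtrip)."""
    path = Path(path)
    rows = []
    for c in spec.components:
        row = dict.fromkeys(TEMPLATE_COLUMNS, "")
        row.update(name=c.name, cas=c.cas or "", component_type="substance",
                   physical_state="", composition_percent=round(c.fraction * 100.0, 10),
                   molecular_weight="" if c.mw is None else c.mw)
        if c.endpoint_value is not None:
            row.update(endpoint_type=spec.endpoint_type,
                       endpoint_value=c.endpoint_value.value,
                       endpoint_unit=c.endpoint_value.unit)
        if c.drc is not None:
            row.update(drc_model=c.drc.model_id, drc_unit=c.drc.conc_unit,
                       alpha=c.drc.params[0], beta=c.drc.params[1])
            if len(c.drc.params) > 2:
                row["gamma"] = c.drc.params[2]
            if len(c.drc.params) > 3:
                row["delta"] = c.drc.params[3]
        rows.append(row)
    df = pd.DataFrame(rows, columns=TEMPLATE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# product_name: {spec.product_name}\n")
        fh.write(f"# output_unit: {spec.output_unit}\n")
        fh.write(f"# endpoint_type: {spec.endpoint_type}\n")
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Structures

def read_structures(path: str | Path) -> list[tuple[str | None, str]]:
    """Read structures from a SMILES list, MOL or SDF file.

    Returns ``(key, smiles)`` pairs where ``key`` is a CAS number when the
    record carries one (second SMILES column or an SDF ``CAS`` property),
    else ``None``; association with components is by CAS when available,
    by order otherwise.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    out: list[tuple[str | None, str]] = []
    if suffix in (".smi", ".smiles", ".txt"):
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                raise ValueError(f"{path.name} line {i + 1}: unparseable SMILES {parts[0]!r}")
            out.append((parts[1] if len(parts) > 1 else None, parts[0]))
    elif suffix == ".mol":
        mol = Chem.MolFromMolFile(str(path))
        if mol is None:
            raise ValueError(f"{path.name}: unparseable MOL block")
        out.append((None, Chem.MolToSmiles(mol)))
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{path.name}: record {i + 1} failed to parse")
            key = mol.GetProp("CAS") if mol.HasProp("CAS") else None
            out.append((key, Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unsupported structure format: {suffix!r} (use .smi/.mol/.sdf)")
    return out


def attach_structures(spec: MixtureSpec, path: str | Path) -> MixtureSpec:
    """Return a spec with structures attached by CAS key or by record order."""
    from dataclasses import replace

    records = read_structures(path)
    keys = [k for k, _ in records]
    comps = list(spec.components)
    if all(k is not None for k in keys):
        by_cas = dict(records)
        missing = [c.name for c in comps if c.cas not in by_cas]
        if missing:
            raise ValueError(f"no structure record for component(s): {missing}")
        comps = [replace(c, structure=by_cas[c.cas]) for c in comps]
    else:
        if len(records) != len(comps):
            raise ValueError(
                f"structure record count ({len(records)}) does not match "
                f"component count ({len(comps)})"
            )
        comps = [replace(c, structure=s) for c, (_, s) in zip(comps, records)]
    return replace(spec, components=tuple(comps))


# ---------------------------------------------------------------------------
# Report

def _fmt(v: float) -> str:
    return f"{v:.3f}"


def results_table(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Effect-grid table: one row per effect %, one column per model with
    ``value [low; high]`` formatting when confidence intervals exist."""
    grid = sorted({e for r in results for e in r.effect_percent if r.model != "SimpleCA"})
    data: dict[str, list[str]] = {"Toxic effect (%)": [f"{e:g}" for e in grid]}
    for r in results:
        if r.model == "SimpleCA":
            continue
        col = []
        lut = dict(zip(r.effect_percent, r.concentrations))
        lo = dict(zip(r.effect_percent, r.ci_low)) if r.ci_low else {}
        hi = dict(zip(r.effect_percent, r.ci_high)) if r.ci_high else {}
        for e in grid:
            if e not in lut:
                col.append("")
            elif e in lo and math.isfinite(lo[e]):
                col.append(f"{_fmt(lut[e])} [{_fmt(lo[e])}; {_fmt(hi[e])}]")
            else:
                col.append(_fmt(lut[e]))
        data[r.model] = col
    return pd.DataFrame(data)


def write_report(
    results: Sequence[PredictionResult],
    spec: MixtureSpec,
    outdir: str | Path,
    plot: bool = True,
) -> dict[str, Path]:
    """Emit the report bundle: summary text, effect-grid table (CSV and
    spreadsheet), machine-readable JSON, and an optional curve plot."""
    if not results:
        raise ValueError("no prediction results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    lowest = lowest_predicted_ecx(results)
    top = sorted(spec.components, key=lambda c: -c.fraction)[:5]
    curve_results = [r for r in results if r.model != "SimpleCA" and r.concentrations]

    lines = [f"Product: {spec.product_name}",
             f"Endpoint: {spec.endpoint_type}  |  output unit: {spec.output_unit}",
             f"Components: {len(spec.components)}",
             "Top composition (by fraction):"]
    for c in top:
        lines.append(f"  - {c.name} ({c.cas or 'no CAS'}): {c.fraction * 100:.3f}%")
    if lowest is not None:
        lines.append(
            f"Lowest predicted {spec.endpoint_type}: {lowest:.3f} {spec.output_unit} "
            f"(minimum across models: {', '.join(r.model for r in results)})"
        )
    for r in results:
        if r.model == "SimpleCA" and r.concentrations:
            lines.append(
                f"Simple CA {spec.endpoint_type}: {r.concentrations[0]:.3f} "
                f"{spec.output_unit} (scalar; no mixture curve)"
            )
        elif r.note:
            lines.append(f"{r.model}: {r.note}")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n", encoding="utf-8")
    files["summary"] = summary

    if curve_results:
        table = results_table(curve_results)
        files["table_csv"] = outdir / "effect_grid.csv"
        table.to_csv(files["table_csv"], index=False)
        files["table_xlsx"] = outdir / "effect_grid.xlsx"
        table.to_excel(files["table_xlsx"], index=False)

    payload = {
        "product_name": spec.product_name,
        "output_unit": spec.output_unit,
        "endpoint_type": spec.endpoint_type,
        "lowest_predicted_ecx": lowest,
        "components": [
            {"name": c.name, "cas": c.cas, "fraction": c.fraction, "mw": c.mw}
            for c in spec.components
        ],
        "results": [
            {
                "model": r.model,
                "unit": r.unit,
                "effect_percent": list(r.effect_percent),
                "concentrations": list(r.concentrations),
                "ci_low": list(r.ci_low) if r.ci_low else None,
                "ci_high": list(r.ci_high) if r.ci_high else None,
                "note": r.note,
            }
            for r in results
        ],
    }
    files["json"] = outdir / "report.json"
    files["json"].write_text(json.dumps(payload, indent=2), encoding="utf-8")

    if plot and curve_results:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for r in curve_results:
            ax.plot(r.concentrations, r.effect_percent, marker="o", label=r.model)
        ax.set_xscale("log")
        ax.set_xlabel(f"mixture concentration ({spec.output_unit})")
        ax.set_ylabel("toxic effect (%)")
        ax.set_title(spec.product_name)
        ax.legend()
        fig.tight_layout()
        files["plot"] = outdir / "predicted_drc.png"
        fig.savefig(files["plot"], dpi=150)
        plt.close(fig)

    return files
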