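"""Strain tables and Pareto-front export/import.

``strain_table`` mirrors the layout of the published strain tables: a
wild-type reference row first, then archived strains in ascending order of
knockout count, with percent variations versus wild type rounded to two
decimals and recomputable from the raw fluxes in the same export.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import pandas as pd

from .loci import same_chromosome_score
from .metrics import wt_variation
from .model import StrainDesign
from .moea import EvaluatedStrain, ParetoArchive

__all__ = ["strain_table", "export_front", "import_front"]


def _fmt_pct(value: float) -> float | None:
    return None if math.isnan(value) else round(value, 2)


def strain_table(
    archive: ParetoArchive,
    loci: dict | None = None,
    decimals: int = 6,
) -> pd.DataFrame:
    """One row per archived strain, wild type first, ascending knockout count."""
    if len(archive) == 0:
        raise ValueError("cannot tabulate an empty archive")
    wt = archive.wt
    if wt is None or wt.metrics is None:
        raise ValueError("archive carries no wild-type reference")

    rows: list[dict[str, Any]] = []

    def record(label: str, strain: EvaluatedStrain) -> dict[str, Any]:
        m = strain.metrics
        row: dict[str, Any] = {
            "strain": label,
            "biomass": round(m.growth_rate, decimals),
            "biomass_wt_var_pct": _fmt_pct(
                wt_variation(m.growth_rate, wt.metrics.growth_rate)
            ),
            "product_flux": round(m.product_flux, decimals),
            "yield": round(m.yield_value, decimals),
            "productivity": round(m.productivity, decimals),
        }
        if m.productivity_range is not None:
            row["min_productivity"] = round(m.productivity_range[0], decimals)
            row["max_productivity"] = round(m.productivity_range[1], decimals)
        for met, val in m.cofactor_production.items():
            row[f"{met}_production"] = round(val, decimals)
            row[f"{met}_wt_var_pct"] = _fmt_pct(
                wt_variation(val, wt.metrics.cofactor_production.get(met, 0.0))
            )
        row["n_knockouts"] = strain.design.n_deletions
        row["knockouts"] = ";".join(sorted(strain.design.deletions))
        if loci is not None:
            row["chromosome_score"] = round(
                same_chromosome_score(strain.design, loci), decimals
            )
        return row

    rows.append(record("WT", wt))
    members = sorted(
        archive.members(), key=lambda s: (s.design.n_deletions, s.sort_key())
    )
    for i, strain in enumerate(members, start=1):
        rows.append(record(str(i), strain))
    return pd.DataFrame(rows)


def _strain_to_dict(strain: EvaluatedStrain) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "deletions": sorted(strain.design.deletions),
        "knockins": sorted(strain.design.knockins),
        "objectives": list(strain.objectives),
        "feasible": strain.feasible,
    }
    if strain.metrics is not None:
        m = strain.metrics
        doc["metrics"] = {
            "growth_rate": m.growth_rate,
            "product_flux": m.product_flux,
            "carbon_uptake": m.carbon_uptake,
            "yield": m.yield_value,
            "productivity": m.productivity,
            "productivity_range": list(m.productivity_range)
            if m.productivity_range is not None
            else None,
            "cofactor_production": dict(m.cofactor_production),
            "n_knockouts": m.n_knockouts,
        }
    return doc


def _strain_from_dict(doc: dict[str, Any]) -> EvaluatedStrain:
    from .metrics import StrainMetrics

    metrics = None
    if doc.get("metrics") is not None:
        m = doc["metrics"]
        rng = m.get("productivity_range")
        metrics = StrainMetrics(
            growth_rate=m["growth_rate"],
            product_flux=m["product_flux"],
            carbon_uptake=m["carbon_uptake"],
            yield_value=m["yield"],
            productivity=m["productivity"],
            productivity_range=tuple(rng) if rng is not None else None,
            cofactor_production=dict(m.get("cofactor_production", {})),
            n_knockouts=m.get("n_knockouts", len(doc["deletions"])),
        )
    return EvaluatedStrain(
        design=StrainDesign(frozenset(doc["deletions"]), frozenset(doc["knockins"])),
        objectives=tuple(doc["objectives"]),
        feasible=doc["feasible"],
        metrics=metrics,
    )


def export_front(archive: ParetoArchive, path: str | Path, format: str = "json") -> None:
    """Write the archive to disk; JSON round-trips losslessly, CSV is tabular."""
    path = Path(path)
    if format == "json":
        doc = {
            "directions": list(archive.directions),
            "wild_type": _strain_to_dict(archive.wt) if archive.wt is not None else None,
            "strains": [_strain_to_dict(s) for s in archive.members()],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    elif format == "csv":
        records = []
        for s in archive.members():
            rec: dict[str, Any] = {
                f"objective_{i}": v for i, v in enumerate(s.objectives)
            }
            rec["n_knockouts"] = s.design.n_deletions
            rec["knockouts"] = ";".join(sorted(s.design.deletions))
            rec["knockins"] = ";".join(sorted(s.design.knockins))
            records.append(rec)
        columns = None
        if not records:  # header-only CSV for an empty archive
            columns = ["n_knockouts", "knockouts", "knockins"]
        pd.DataFrame(records, columns=columns).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_front(path: str | Path) -> ParetoArchive:
    """Rebuild an archive from a JSON export."""
    doc = json.loads(Path(path).read_text())
    wt = (
        _strain_from_dict(doc["wild_type"]) if doc.get("wild_type") is not None else None
    )
    archive = ParetoArchive(tuple(doc["directions"]), wt=wt)
    for sdoc in doc["strains"]:
        archive.add(_strain_from_dict(sdoc))
    return archive
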