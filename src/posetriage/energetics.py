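"""Binding-energy bookkeeping and correlation statistics.

The MM-GBSA binding energy is the component difference

    dG_bind = G_complex - G_protein - G_ligand          (kcal/mol),

with component tables produced by external engines and consumed here from
CSV. The module validates component consistency on ingest, forms the
pre/post-optimisation difference ddG = dG_QM-MM - dG_Glide, and computes the
rank (Spearman, average ranks on ties) and squared Pearson correlations used
to compare energy scales.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_COMPONENT_TOL = 1e-9


class EnergyError(ValueError):
    """Raised for missing or inconsistent energy components."""


@dataclass
class EnergyRecord:
    """Energies of one pose from one source (kcal/mol)."""

    pose_key: tuple[str, int]
    source: str                      # glide | qmmm | other
    g_complex: float | None = None
    g_protein: float | None = None
    g_ligand: float | None = None
    dg_bind: float | None = None
    de_interaction: float | None = None   # ligand-residue interaction energy
    pic50: float | None = None

    def __post_init__(self) -> None:
        comps = (self.g_complex, self.g_protein, self.g_ligand)
        if all(c is not None for c in comps) and self.dg_bind is not None:
            expect = self.g_complex - self.g_protein - self.g_ligand
            if abs(self.dg_bind - expect) > _COMPONENT_TOL:
                raise EnergyError(
                    f"pose {self.pose_key} ({self.source}): dG_bind {self.dg_bind} "
                    f"inconsistent with components ({expect})")


def delta_g(rec: EnergyRecord) -> float:
    """dG_bind = G_complex - G_protein - G_ligand; stored into the record."""
    comps = (rec.g_complex, rec.g_protein, rec.g_ligand)
    if any(c is None for c in comps):
        raise EnergyError(f"pose {rec.pose_key}: missing energy component")
    rec.dg_bind = rec.g_complex - rec.g_protein - rec.g_ligand
    return rec.dg_bind


def delta_delta_g(glide: EnergyRecord, qmmm: EnergyRecord) -> float:
    """ddG = dG_QM-MM - dG_Glide for one pose."""
    if glide.pose_key != qmmm.pose_key:
        raise EnergyError(f"pose mismatch: {glide.pose_key} vs {qmmm.pose_key}")
    if glide.dg_bind is None or qmmm.dg_bind is None:
        raise EnergyError(f"pose {glide.pose_key}: dG missing")
    return qmmm.dg_bind - glide.dg_bind


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks on ties, in [-1, 1].

    A constant vector leaves the coefficient undefined: NaN is returned and
    a warning logged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise EnergyError("rank_correlation needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("rank correlation undefined for constant input")
        return math.nan
    r, _ = stats.spearmanr(x, y)
    return float(r)


def rsq(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of the least-squares fit of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise EnergyError("rsq needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("r^2 undefined for zero-variance input")
        return math.nan
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

ENERGY_COLUMNS = ["ligand_id", "pose_id", "source", "G_complex", "G_protein",
                  "G_ligand", "dG", "dE", "pIC50"]


def read_energies(path: str | Path) -> list[EnergyRecord]:
    """Read an energies CSV (columns ligand_id, pose_id, source, G_complex,
    G_protein, G_ligand, dG, dE, pIC50; the last five optional per row)."""
    df = pd.read_csv(path)
    missing = {"ligand_id", "pose_id", "source"} - set(df.columns)
    if missing:
        raise EnergyError(f"{path}: missing columns {sorted(missing)}")

    def get(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    records = []
    for _, row in df.iterrows():
        rec = EnergyRecord(
            pose_key=(str(row["ligand_id"]), int(row["pose_id"])),
            source=str(row["source"]),
            g_complex=get(row, "G_complex"), g_protein=get(row, "G_protein"),
            g_ligand=get(row, "G_ligand"), dg_bind=get(row, "dG"),
            de_interaction=get(row, "dE"), pic50=get(row, "pIC50"))
        if rec.dg_bind is None and rec.g_complex is not None:
            delta_g(rec)
        records.append(rec)
    return records


def write_energies(records: Sequence[EnergyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({"ligand_id": r.pose_key[0], "pose_id": r.pose_key[1],
                     "source": r.source, "G_complex": r.g_complex,
                     "G_protein": r.g_protein, "G_ligand": r.g_ligand,
                     "dG": r.dg_bind, "dE": r.de_interaction, "pIC50": r.pic50})
    pd.DataFrame(rows, columns=ENERGY_COLUMNS).to_csv(path, index=False)


def compare_sources(records: Sequence[EnergyRecord],
                    source_a: str = "glide", source_b: str = "qmmm") -> pd.DataFrame:
    """Per-pose ddG table between two energy sources (b minus a)."""
    a = {r.pose_key: r for r in records if r.source == source_a}
    b = {r.pose_key: r for r in records if r.source == source_b}
    rows = []
    for key in sorted(a.keys() & b.keys()):
        rows.append({"ligand_id": key[0], "pose_id": key[1],
                     f"dG_{source_a}": a[key].dg_bind, f"dG_{source_b}": b[key].dg_bind,
                     "ddG": delta_delta_g(a[key], b[key])})
    return pd.DataFrame(rows)
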