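"""Comparative amino-acid enrichment over paired design ensembles.

Sequence-optimization runs performed with the substrate locked in the
pro-S binding mode and, separately, in the pro-R mode each yield a large
set of low-energy sequence solutions over the designable active-site
positions.  Substitutions that support one binding mode over the other
show up as frequency differences between the two sets.  This module
computes, per position and amino acid,

    PE(p, aa) = 100 * (f_target(p, aa) - f_other(p, aa))

(the signed percentage-point enrichment toward the target mode, i.e. the
difference in amino-acid abundance between the two design sets), flags
substitutions found exclusively in one set, and ranks candidate mutations.

Frequencies are computed over *unique* sequences: redundant copies of the
same sequence are first trimmed keeping only the lowest-energy record, so
heavily resampled designs do not dominate the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")

PRO_S_MODE = "pro_S"
PRO_R_MODE = "pro_R"


@dataclass(frozen=True)
class DesignRecord:
    design_id: str
    residues: dict            # position (1-based residue number) -> one-letter AA
    energy: float             # score units, lower is better
    trajectory_id: Optional[str] = None

    def sequence_key(self, positions: Sequence[int]) -> tuple:
        return tuple(self.residues[p] for p in positions)


@dataclass
class DesignEnsemble:
    mode: str
    designable_positions: tuple
    records: list
    deduped: bool = False

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FrequencyTable:
    """Per-position amino-acid frequencies (rows: positions, cols: 20 AAs)."""

    freq: pd.DataFrame
    counts: pd.DataFrame
    n_designs: int


@dataclass
class EnrichmentTable:
    """Signed percentage-point enrichment toward ``target_mode``."""

    pe: pd.DataFrame
    target_mode: str
    other_mode: str


@dataclass
class CandidateReport:
    """Ranked candidate substitutions; rows ordered by the ranking rule."""

    table: pd.DataFrame
    min_count: int
    top_k: int


# ---------------------------------------------------------------------------
# loading and dedup
# ---------------------------------------------------------------------------

def load_designs(path, mode: str,
                 designable_positions: Optional[Sequence[int]] = None) -> DesignEnsemble:
    """Load a design ensemble from a tab-separated table.

    Expected header: ``design_id``, one column per designable position
    (header is the 1-based residue number), and ``energy``.  Optionally a
    ``trajectory_id`` column.  Positions default to every numeric column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "design_id" not in df.columns or "energy" not in df.columns:
        raise ConfigurationError(f"{path}: need 'design_id' and 'energy' columns")
    numeric_cols = [c for c in df.columns if str(c).strip().isdigit()]
    if designable_positions is None:
        positions = tuple(sorted(int(c) for c in numeric_cols))
    else:
        positions = tuple(designable_positions)
        missing = [p for p in positions if str(p) not in df.columns]
        if missing:
            raise ConfigurationError(f"{path}: missing position columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rowd = dict(zip(df.columns, row))
        residues = {}
        for p in positions:
            aa = str(rowd[str(p)]).strip().upper()
            if aa not in AA_ALPHABET:
                raise ConfigurationError(
                    f"{path}, line {i}: invalid amino acid {aa!r} at position {p}")
            residues[p] = aa
        try:
            energy = float(rowd["energy"])
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"{path}, line {i}: non-numeric energy {rowd['energy']!r}")
        records.append(DesignRecord(
            design_id=str(rowd["design_id"]), residues=residues, energy=energy,
            trajectory_id=str(rowd["trajectory_id"]) if "trajectory_id" in rowd
            and pd.notna(rowd["trajectory_id"]) else None))
    return DesignEnsemble(mode=mode, designable_positions=positions,
                          records=records, deduped=False)


def save_designs(ensemble: DesignEnsemble, path) -> None:
    """Write an ensemble in the tab-separated layout :func:`load_designs` reads."""
    cols = {"design_id": [r.design_id for r in ensemble.records]}
    for p in ensemble.designable_positions:
        cols[str(p)] = [r.residues[p] for r in ensemble.records]
    cols["energy"] = [r.energy for r in ensemble.records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def dedupe_lowest_energy(ensemble: DesignEnsemble) -> DesignEnsemble:
    """Keep one record per distinct sequence: the lowest-energy copy.

    Energy ties are broken by first occurrence.  Survivors are ordered by
    ascending energy (stable, so tied survivors keep input order).
    """
    best: dict[tuple, tuple[int, DesignRecord]] = {}
    for i, rec in enumerate(ensemble.records):
        key = rec.sequence_key(ensemble.designable_positions)
        if key not in best or rec.energy < best[key][1].energy:
            if key in best:
                best[key] = (best[key][0], rec)   # keep original index for stability
            else:
                best[key] = (i, rec)
    survivors = sorted(best.values(), key=lambda t: (t[1].energy, t[0]))
    return DesignEnsemble(mode=ensemble.mode,
                          designable_positions=ensemble.designable_positions,
                          records=[rec for _, rec in survivors], deduped=True)


# ---------------------------------------------------------------------------
# frequencies and enrichment
# ---------------------------------------------------------------------------

def frequency_table(ensemble: DesignEnsemble) -> FrequencyTable:
    """Per-position amino-acid frequencies over the unique sequences.

    The ensemble must be deduped first: frequencies are defined over unique
    sequences, matching the trim-then-count order of operations.
    """
    if not ensemble.deduped:
        raise ValueError("frequency_table requires a deduped ensemble; "
                         "apply dedupe_lowest_energy first")
    if len(ensemble) == 0:
        raise ValueError("cannot compute frequencies of an empty ensemble")
    positions = list(ensemble.designable_positions)
    data = {}
    for p in positions:
        col = pd.Series([rec.residues[p] for rec in ensemble.records])
        data[p] = col.value_counts().reindex(AA_ALPHABET, fill_value=0)
    counts = pd.DataFrame(data).T
    counts.index.name = "position"
    counts.columns.name = "aa"
    return FrequencyTable(freq=counts / len(ensemble), counts=counts,
                          n_designs=len(ensemble))


def percentage_enrichment(freq_target: FrequencyTable,
                          freq_other: FrequencyTable,
                          target_mode: str = PRO_S_MODE,
                          other_mode: str = PRO_R_MODE) -> EnrichmentTable:
    """PE(p, aa) = 100 * (f_target - f_other), in percentage points."""
    if not freq_target.freq.index.equals(freq_other.freq.index):
        raise ValueError(
            f"position mismatch: {list(freq_target.freq.index)} vs "
            f"{list(freq_other.freq.index)}")
    pe = 100.0 * (freq_target.freq - freq_other.freq)
    return EnrichmentTable(pe=pe, target_mode=target_mode, other_mode=other_mode)


def exclusive_substitutions(freq_s: FrequencyTable, freq_r: FrequencyTable,
                            min_count: int = 1) -> list[tuple]:
    """Substitutions present >= min_count times in one set and absent (0) from the other.

    Returns ``(position, aa, mode)`` tuples where ``mode`` names the set
    that contains the substitution.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not freq_s.counts.index.equals(freq_r.counts.index):
        raise ValueError("position mismatch between frequency tables")
    out = []
    for p in freq_s.counts.index:
        for aa in AA_ALPHABET:
            cs = int(freq_s.counts.loc[p, aa])
            cr = int(freq_r.counts.loc[p, aa])
            if cs >= min_count and cr == 0:
                out.append((int(p), aa, PRO_S_MODE))
            elif cr >= min_count and cs == 0:
                out.append((int(p), aa, PRO_R_MODE))
    return out


def comparative_table(freq_s: FrequencyTable, freq_r: FrequencyTable) -> pd.DataFrame:
    """Per position, the amino acid most enriched toward each mode and its PE.

    Ties on the maximum PE are broken alphabetically and flagged in the
    ``tie_S`` / ``tie_R`` columns.
    """
    pe_s = percentage_enrichment(freq_s, freq_r).pe
    rows = []
    for p in pe_s.index:
        row_s = pe_s.loc[p]
        row_r = -row_s
        best_s = row_s.max()
        best_r = row_r.max()
        cands_s = sorted(row_s.index[np.isclose(row_s, best_s)])
        cands_r = sorted(row_r.index[np.isclose(row_r, best_r)])
        rows.append({
            "position": int(p),
            "preferred_aa_S": cands_s[0], "pe_S": float(best_s),
            "tie_S": len(cands_s) > 1,
            "preferred_aa_R": cands_r[0], "pe_R": float(best_r),
            "tie_R": len(cands_r) > 1,
        })
    return pd.DataFrame(rows)


def rank_candidates(freq_s: FrequencyTable, freq_r: FrequencyTable,
                    min_count: int = 3, top_k: int = 20) -> CandidateReport:
    """Rank (position, aa) substitutions as pro-S selectivity candidates.

    Sort order: exclusive-to-pro-S first, then descending PE toward pro-S,
    then position, then amino acid.  Substitutions absent from both sets
    are not listed.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    pe = percentage_enrichment(freq_s, freq_r).pe
    exclusives = {(p, aa) for p, aa, mode in
                  exclusive_substitutions(freq_s, freq_r, min_count=min_count)
                  if mode == PRO_S_MODE}
    rows = []
    for p in pe.index:
        for aa in AA_ALPHABET:
            cs = int(freq_s.counts.loc[p, aa])
            cr = int(freq_r.counts.loc[p, aa])
            if cs == 0 and cr == 0:
                continue
            rows.append({
                "position": int(p), "aa": aa,
                "f_S": float(freq_s.freq.loc[p, aa]),
                "f_R": float(freq_r.freq.loc[p, aa]),
                "PE_S": float(pe.loc[p, aa]),
                "exclusive_S": (int(p), aa) in exclusives,
                "count_S": cs, "count_R": cr,
            })
    df = pd.DataFrame(rows)
    df = df.sort_values(by=["exclusive_S", "PE_S", "position", "aa"],
                        ascending=[False, False, True, True],
                        kind="mergesort").head(top_k).reset_index(drop=True)
    return CandidateReport(table=df, min_count=min_count, top_k=top_k)
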