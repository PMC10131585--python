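"""Candidate-table bookkeeping and screening analytics.

Holds the per-candidate screening records (sequence, design cycle, external
Rosetta score, time bound, MM-GBSA energy, optional rigorous free energy),
the ranking/shortlisting rules, the time-bound vs energy correlation, and
per-position amino-acid frequency (sequence-logo) matrices.

The reference candidate table shipped with the package lists the 20
screening entries for the CTLA4-binding cyclic peptide campaign: three
template entries (T0-T2, the cyclized B7-2 fragment) and 17 designed
peptides. Peptide 16 never dissociated within the 2 us screening budget,
so its time bound is censored at the recorded value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COLUMNS = [
    "id", "sequence", "design_cycles", "rosetta_score", "time_bound_ns",
    "censored", "dg_mmgbsa", "dg_mmgbsa_sem", "dg_rigorous", "dg_rigorous_unc",
]


@dataclass
class CandidateRecord:
    id: str
    sequence: str
    design_cycles: int = 0
    rosetta_score: float = float("nan")
    time_bound: float = 0.0
    censored: bool = False
    dg_mmgbsa: float = float("nan")
    dg_mmgbsa_sem: float = float("nan")
    dg_rigorous: Optional[float] = None
    dg_rigorous_unc: Optional[float] = None

    def __post_init__(self):
        bad = [c for c in self.sequence if c not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"candidate {self.id}: non-canonical letters {bad}")
        if self.time_bound < 0:
            raise ValueError("time_bound must be >= 0")


def _records_from_frame(df: pd.DataFrame) -> List[CandidateRecord]:
    records = []
    for row in df.itertuples(index=False):
        rig = getattr(row, "dg_rigorous", None)
        rig_u = getattr(row, "dg_rigorous_unc", None)
        records.append(CandidateRecord(
            id=str(row.id), sequence=str(row.sequence),
            design_cycles=int(row.design_cycles),
            rosetta_score=float(row.rosetta_score),
            time_bound=float(row.time_bound_ns),
            censored=bool(int(row.censored)),
            dg_mmgbsa=float(row.dg_mmgbsa),
            dg_mmgbsa_sem=float(row.dg_mmgbsa_sem),
            dg_rigorous=None if rig is None or pd.isna(rig) else float(rig),
            dg_rigorous_unc=None if rig_u is None or pd.isna(rig_u) else float(rig_u),
        ))
    return records


def read_candidate_table(source) -> List[CandidateRecord]:
    """Read a candidate table (TSV mirroring the screening-table columns)."""
    df = pd.read_csv(source, sep="\t", dtype={"id": str})
    missing = set(_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    return _records_from_frame(df)


def reference_candidates() -> List[CandidateRecord]:
    """The packaged 20-entry screening table (3 templates + 17 designed)."""
    text = resources.files("cycbind").joinpath("data/candidates.tsv").read_text()
    return read_candidate_table(io.StringIO(text))


def screen_table_report(records: Sequence[CandidateRecord]) -> str:
    """Render records as TSV; round-trips losslessly through the reader.

    Censored entries (bound at simulation end) keep their flag column;
    absent rigorous free energies render as blank cells.
    """
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "sequence": r.sequence, "design_cycles": r.design_cycles,
            "rosetta_score": r.rosetta_score, "time_bound_ns": r.time_bound,
            "censored": int(r.censored), "dg_mmgbsa": r.dg_mmgbsa,
            "dg_mmgbsa_sem": r.dg_mmgbsa_sem,
            "dg_rigorous": "" if r.dg_rigorous is None else r.dg_rigorous,
            "dg_rigorous_unc": "" if r.dg_rigorous_unc is None else r.dg_rigorous_unc,
        })
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.to_csv(sep="\t", index=False)


Selector = Union[str, Callable[[CandidateRecord], bool]]


def select_records(records: Sequence[CandidateRecord], subset: Selector = "all"):
    if callable(subset):
        return [r for r in records if subset(r)]
    if subset == "all":
        return list(records)
    if subset == "designed":
        # template entries are conventionally labelled T0, T1, ...
        return [r for r in records if not r.id.upper().startswith("T")]
    raise ValueError(f"unknown subset {subset!r}")


def correlation_time_vs_energy(
    records: Sequence[CandidateRecord],
    subset: Selector = "designed",
) -> float:
    """Sample Pearson correlation between time bound and MM-GBSA energy.

    Returns the signed value (negative: longer binding goes with more
    favorable energy); callers wanting the magnitude take ``abs``.
    Censored times enter at their recorded value.
    """
    sel = select_records(records, subset)
    if len(sel) < 3:
        raise ValueError("need >= 3 records for a meaningful correlation")
    t = np.array([r.time_bound for r in sel])
    g = np.array([r.dg_mmgbsa for r in sel])
    if np.ptp(t) == 0 or np.ptp(g) == 0:
        raise ValueError("zero variance in time bound or energy column")
    return float(np.corrcoef(t, g)[0, 1])


def shortlist(records: Sequence[CandidateRecord]) -> Dict[str, List[str]]:
    """Candidates advanced to rigorous free-energy calculation.

    Picks the record(s) with the lowest MM-GBSA energy and the record(s)
    with the longest time bound; a censored time outranks any uncensored
    record with equal or lower recorded time. Ties return all tied ids,
    ordered by id.
    """
    if not records:
        raise ValueError("empty candidate list")
    best_dg = min(r.dg_mmgbsa for r in records)
    lowest = sorted(r.id for r in records if r.dg_mmgbsa == best_dg)
    best_time_key = max((r.time_bound, r.censored) for r in records)
    longest = sorted(r.id for r in records if (r.time_bound, r.censored) == best_time_key)
    return {"lowest_mmgbsa": lowest, "longest_bound": longest}


@dataclass
class LogoMatrix:
    """Per-position amino-acid frequencies over an aligned sequence set."""

    frequencies: np.ndarray  # (positions, 20)
    n_sequences: int
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each position's frequencies must sum to 1")
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    def frequency(self, position: int, letter: str) -> float:
        """1-based position, one-letter amino acid."""
        return float(self.frequencies[position - 1, self.alphabet.index(letter)])


def logo_frequencies(sequences: Sequence[str]) -> LogoMatrix:
    """Position-wise amino-acid occurrence frequencies (count / n)."""
    if not sequences:
        raise ValueError("no sequences given")
    length = len(sequences[0])
    offenders = [s for s in sequences if len(s) != length]
    if offenders:
        raise ValueError(f"sequences of differing length: {offenders}")
    freq = np.zeros((length, len(AMINO_ACIDS)))
    for s in sequences:
        for pos, letter in enumerate(s.upper()):
            if letter not in AMINO_ACIDS:
                raise ValueError(f"non-canonical letter {letter!r} in {s!r}")
            freq[pos, AMINO_ACIDS.index(letter)] += 1
    return LogoMatrix(frequencies=freq / len(sequences), n_sequences=len(sequences))
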