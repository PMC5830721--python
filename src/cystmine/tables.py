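"""Fixed-format TSV output tables for scan results.

Column orders are part of the tool's contract and are stable across runs;
rows are pre-sorted by the scan, so re-running on unchanged inputs yields
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .mining import BondObservation, StructureVerdict, UniqueBond

__all__ = [
    "BOND_COLUMNS",
    "OBSERVATION_COLUMNS",
    "VERDICT_COLUMNS",
    "bonds_frame",
    "observations_frame",
    "verdicts_frame",
    "write_tsv",
]

BOND_COLUMNS = [
    "accession", "pos_i", "pos_j", "labile",
    "n_present", "n_filtered_length", "n_missing",
    "n_excluded_truncated", "n_excluded_mutated", "n_excluded_unresolved",
    "same_file_lability", "in_reference",
    "representative_pdb", "representative_chain",
    "chi1", "chi2", "chi3", "chi2p", "chi1p",
    "alpha1", "alpha2", "d", "dse",
    "config", "config_boundary", "b_avg", "ss_pair",
]

OBSERVATION_COLUMNS = [
    "accession", "pos_i", "pos_j", "pdb_id", "chain", "status",
    "resolution", "d", "dse", "config", "b_avg", "ss_pair",
]

VERDICT_COLUMNS = ["pdb_id", "status", "reasons"]

_ANGLE_FMT = "{:.3f}"


def _fmt(value, fmt: str = _ANGLE_FMT) -> str:
    return "" if value is None else fmt.format(value)


def bonds_frame(bonds: Sequence[UniqueBond]) -> pd.DataFrame:
    rows = []
    for bond in bonds:
        geom = bond.geometry
        row = {
            "accession": bond.accession,
            "pos_i": bond.pos_i,
            "pos_j": bond.pos_j,
            "labile": bond.labile,
            "n_present": bond.count("present"),
            "n_filtered_length": bond.count("present_filtered_length"),
            "n_missing": bond.count("missing"),
            "n_excluded_truncated": bond.count("excluded_truncated"),
            "n_excluded_mutated": bond.count("excluded_mutated"),
            "n_excluded_unresolved": bond.count("excluded_unresolved"),
            "same_file_lability": bond.same_file_lability,
            "in_reference": bond.in_reference,
            "representative_pdb": bond.representative.pdb_id if bond.representative else "",
            "representative_chain": bond.representative.chain if bond.representative else "",
        }
        if geom is not None:
            row.update(
                chi1=geom.chi1, chi2=geom.chi2, chi3=geom.chi3,
                chi2p=geom.chi2p, chi1p=geom.chi1p,
                alpha1=geom.alpha1, alpha2=geom.alpha2,
                d=geom.d, dse=geom.dse,
                config=geom.config, config_boundary=geom.config_boundary,
                b_avg=geom.b_avg, ss_pair=geom.ss_pair,
            )
        else:
            row.update({c: None for c in BOND_COLUMNS[14:]})
        rows.append(row)
    return pd.DataFrame(rows, columns=BOND_COLUMNS)


def observations_frame(observations: Sequence[BondObservation]) -> pd.DataFrame:
    rows = []
    for obs in observations:
        geom = obs.geometry
        rows.append(
            {
                "accession": obs.accession,
                "pos_i": obs.pos_i,
                "pos_j": obs.pos_j,
                "pdb_id": obs.pdb_id,
                "chain": obs.chain,
                "status": obs.status,
                "resolution": obs.resolution,
                "d": geom.d if geom else None,
                "dse": geom.dse if geom else None,
                "config": geom.config if geom else None,
                "b_avg": geom.b_avg if geom else None,
                "ss_pair": geom.ss_pair if geom else None,
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def verdicts_frame(verdicts: Sequence[StructureVerdict]) -> pd.DataFrame:
    rows = [
        {"pdb_id": v.pdb_id, "status": v.status, "reasons": ",".join(v.reasons)}
        for v in verdicts
    ]
    return pd.DataFrame(rows, columns=VERDICT_COLUMNS)


def write_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
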