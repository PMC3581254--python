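"""Per-residue feature assembly for the catalytic-residue classifier.

Feature columns:

* ``AA_*``  -- binary one-hot coding of amino-acid type (alphabetical
  ACDEFGHIKLMNPQRSTVWY order; unknown 'X' codes to all zeros),
* ``Z_SEQ``, ``Z_STR``, ``Z_B`` -- per-protein standardized flexibility
  profiles,
* ``CONS`` -- sequence conservation, the "information per position" column
  of a PSI-BLAST ASCII PSSM.

Named combinations mirror the classifier comparisons: ``AA``, ``SEQ``,
``STR``, ``SEQ+STR``, ``B``, ``AA+SEQ``, ``SEQ+C``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ctxflex.flexibility import FlexibilityProfile
from ctxflex.structure_io import ChainStructure

__all__ = [
    "AA_ORDER", "FEATURE_SETS", "ConservationTrack", "FeatureTable",
    "encode_aa", "parse_pssm", "build_feature_table",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_COLUMNS = [f"AA_{a}" for a in AA_ORDER]

FEATURE_SETS: dict[str, list[str]] = {
    "AA": AA_COLUMNS,
    "SEQ": ["Z_SEQ"],
    "STR": ["Z_STR"],
    "SEQ+STR": ["Z_SEQ", "Z_STR"],
    "B": ["Z_B"],
    "AA+SEQ": AA_COLUMNS + ["Z_SEQ"],
    "SEQ+C": ["Z_SEQ", "CONS"],
}


def encode_aa(aa: str) -> np.ndarray:
    """One-hot encode a one-letter amino-acid code (20-vector).

    Unknown residues ('X' or anything outside the standard alphabet) encode
    to the all-zero vector with a warning for non-'X' codes.
    """
    vec = np.zeros(20)
    idx = AA_ORDER.find(aa)
    if idx >= 0:
        vec[idx] = 1.0
    elif aa != "X":
        warnings.warn(f"unknown amino-acid code {aa!r}; encoded as all-zero")
    return vec


@dataclass
class ConservationTrack:
    """Per-position conservation (information per position, bits >= 0)."""

    values: np.ndarray
    letters: str  # PSSM query sequence, for agreement checking

    def __len__(self) -> int:
        return len(self.values)


def parse_pssm(pssm_path: str | Path) -> ConservationTrack:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``) conservation track.

    Data rows carry: position, residue letter, 20 log-odds scores, 20 weighted
    percentages, information per position, relative-weight column. The
    information-per-position value (second-to-last numeric column) is kept.
    """
    pssm_path = Path(pssm_path)
    if not pssm_path.exists():
        raise FileNotFoundError(pssm_path)
    values: list[float] = []
    letters: list[str] = []
    errors: list[str] = []
    for lineno, line in enumerate(pssm_path.read_text().splitlines(), start=1):
        parts = line.split()
        # data rows start with a position index followed by a residue letter
        if len(parts) < 4 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue
        if not parts[1].isalpha():
            continue
        try:
            # full rows have 44 fields; information per position is field -2
            info = float(parts[-2])
        except ValueError:
            errors.append(f"line {lineno}: trailing columns are not numeric")
            continue
        values.append(info)
        letters.append(parts[1].upper())
    if errors:
        raise ValueError("malformed PSSM rows:\n" + "\n".join(errors))
    if not values:
        raise ValueError(f"no PSSM data rows found in {pssm_path}")
    return ConservationTrack(values=np.array(values), letters="".join(letters))


def align_conservation(chain: ChainStructure, track: ConservationTrack,
                       max_mismatch: float = 0.05) -> np.ndarray:
    """Match a conservation track to a chain by sequential position.

    PSSM files carry no author numbering, so positions map 1:1 in order.
    Letter disagreements are warned about; more than ``max_mismatch`` of
    positions disagreeing (or a length mismatch) is an error.
    """
    if len(track) != len(chain):
        raise ValueError(
            f"PSSM has {len(track)} positions but chain has {len(chain)} residues"
        )
    seq = chain.sequence
    mism = [i for i, (a, b) in enumerate(zip(seq, track.letters)) if a != b and a != "X"]
    if len(mism) > max_mismatch * len(chain):
        raise ValueError(
            f"PSSM sequence disagrees with chain at {len(mism)}/{len(chain)} positions"
        )
    if mism:
        warnings.warn(
            f"PSSM letters differ from chain at {len(mism)} position(s); values kept"
        )
    return track.values


@dataclass
class FeatureTable:
    """Residue-level design matrix with labels and per-protein group keys."""

    X: np.ndarray                      # n_rows x n_features
    y: np.ndarray                      # binary, 1 = catalytic
    feature_names: list[str]
    groups: list[tuple[str, str]]      # (pdb_id, chain_id) per row
    res_keys: list[tuple[int, str]]    # (res_seq, icode) per row

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.groups) == len(self.res_keys) == n):
            raise ValueError("row bookkeeping lengths disagree")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if n and not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def proteins(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            groups=[self.groups[i] for i in idx],
            res_keys=[self.res_keys[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "pdb_id", [g[0] for g in self.groups])
        df.insert(1, "chain_id", [g[1] for g in self.groups])
        df.insert(2, "res_seq", [k[0] for k in self.res_keys])
        df.insert(3, "icode", [k[1] for k in self.res_keys])
        df["y"] = self.y.astype(int)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        meta = ["pdb_id", "chain_id", "res_seq", "icode", "y"]
        names = [c for c in df.columns if c not in meta]
        return cls(
            X=df[names].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=int),
            feature_names=names,
            groups=list(zip(df["pdb_id"].astype(str), df["chain_id"].astype(str))),
            res_keys=list(zip(df["res_seq"].astype(int), df["icode"].astype(str))),
        )


def build_feature_table(
    chains: Sequence[tuple[ChainStructure, FlexibilityProfile, ConservationTrack | None]],
    feature_set: str | Sequence[str] = "SEQ",
) -> FeatureTable:
    """Assemble the residue-level design matrix across chains.

    ``feature_set`` is a named combination (see ``FEATURE_SETS``) or an
    explicit column list. Rows follow input chain order, residues in sequence
    order. Requesting ``CONS`` for a chain without a conservation track is an
    error.
    """
    if isinstance(feature_set, str):
        try:
            columns = FEATURE_SETS[feature_set]
        except KeyError:
            raise ValueError(
                f"unknown feature set {feature_set!r}; known: {sorted(FEATURE_SETS)}"
            ) from None
    else:
        columns = list(feature_set)

    blocks: list[np.ndarray] = []
    y: list[np.ndarray] = []
    groups: list[tuple[str, str]] = []
    res_keys: list[tuple[int, str]] = []
    for item in chains:
        chain, profile, track = (item if len(item) == 3 else (*item, None))
        if len(profile) != len(chain):
            raise ValueError(f"profile/chain length mismatch for {chain.pdb_id}")
        per_col: list[np.ndarray] = []
        tracks = {"Z_SEQ": profile.z_seq, "Z_STR": profile.z_str, "Z_B": profile.z_b}
        cons: np.ndarray | None = None
        for col in columns:
            if col in tracks:
                per_col.append(tracks[col])
            elif col.startswith("AA_"):
                letter = col[3:]
                per_col.append(
                    np.array([1.0 if r.aa == letter else 0.0 for r in chain.residues])
                )
            elif col == "CONS":
                if track is None:
                    raise ValueError(
                        f"feature CONS requested but {chain.pdb_id}:{chain.chain_id} "
                        "has no conservation track"
                    )
                if cons is None:
                    cons = align_conservation(chain, track)
                per_col.append(cons)
            else:
                raise ValueError(f"unknown feature column {col!r}")
        blocks.append(np.column_stack(per_col))
        y.append(chain.labels.astype(int))
        groups.extend([(chain.pdb_id, chain.chain_id)] * len(chain))
        res_keys.extend([(r.res_seq, r.icode) for r in chain.residues])
    return FeatureTable(
        X=np.vstack(blocks),
        y=np.concatenate(y),
        feature_names=list(columns),
        groups=groups,
        res_keys=res_keys,
    )
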