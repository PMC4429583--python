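"""Assembly of the per-transfer feature matrix.

Each analysable floor transfer becomes one row: the response (FTO in ms)
plus 30 predictors — the nine processing measures for T1 and for T2,
eight sequence-organization variables (initiating/responding/backchannel
status of both turns, T2 valence, preference), the two laughter flags,
and the two speaker sexes. Only complete cases enter the model; a drop
log records how many rows each predictor eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .coding import SequenceCodes
from .measures import ProcessingProfile
from .segmentation import FloorTransfer

__all__ = ["PROCESSING_MEASURES", "PREDICTORS", "CATEGORICAL_PREDICTORS",
           "build_feature_matrix", "encode_features", "FeatureBuildError"]

PROCESSING_MEASURES = [
    "duration_ms", "rate_delta", "mean_log_frequency", "mean_concreteness",
    "mean_surprisal", "info_uniformity", "mean_contextual_diversity",
    "tree_height", "n_clauses",
]
SEQUENCE_PREDICTORS = [
    "t1_initiating", "t1_responding", "t1_backchannel",
    "t2_initiating", "t2_responding", "t2_backchannel",
    "t2_valence", "preference",
]
PREDICTORS: List[str] = (
    [f"t1_{m}" for m in PROCESSING_MEASURES]
    + [f"t2_{m}" for m in PROCESSING_MEASURES]
    + SEQUENCE_PREDICTORS
    + ["t1_laughter", "t2_laughter", "t1_sex", "t2_sex"]
)
CATEGORICAL_PREDICTORS = {"t2_valence": ["negative", "none", "positive"],
                          "preference": ["dispreferred", "not_applicable",
                                         "preferred"],
                          "t1_sex": ["female", "male"],
                          "t2_sex": ["female", "male"]}


class FeatureBuildError(RuntimeError):
    pass


def build_feature_matrix(
    transfers: Sequence[FloorTransfer],
    codes: Sequence[SequenceCodes],
    t1_profiles: Sequence[ProcessingProfile],
    t2_profiles: Sequence[ProcessingProfile],
    response: str = "raw",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Build the complete-case feature table and a per-predictor drop log.

    ``response="stripped"`` uses the placeholder-stripped FTO (transfers
    with all-placeholder T2s, which have no stripped FTO, are dropped).
    Categorical predictors are carried as pandas categories, booleans as
    bools. Returns ``(table, drop_log)`` where ``drop_log[name]`` is the
    number of otherwise-usable rows lost to a missing value of ``name``.
    """
    if not (len(transfers) == len(codes) == len(t1_profiles) == len(t2_profiles)):
        raise ValueError("transfers/codes/profiles must be parallel sequences")
    rows = []
    drop_log: Dict[str, int] = {p: 0 for p in PREDICTORS}
    drop_log["fto"] = 0
    n_dropped = 0
    for tr, sc, p1, p2 in zip(transfers, codes, t1_profiles, t2_profiles):
        if response == "stripped":
            fto = None if tr.t2_all_placeholder else tr.fto_stripped_ms
        else:
            fto = tr.fto_ms
        row = {"conversation_id": tr.conversation_id, "fto_ms": fto}
        for prefix, prof, turn in (("t1", p1, tr.t1), ("t2", p2, tr.t2)):
            for m in PROCESSING_MEASURES:
                row[f"{prefix}_{m}"] = getattr(prof, m)
            row[f"{prefix}_sex"] = turn.speaker_sex
        for name in SEQUENCE_PREDICTORS + ["t1_laughter", "t2_laughter"]:
            row[name] = getattr(sc, name)
        missing = [k for k in PREDICTORS if row[k] is None]
        if fto is None:
            missing.append("fto")
        if missing:
            n_dropped += 1
            for k in missing:
                drop_log[k] += 1
            continue
        rows.append(row)
    if not rows:
        raise FeatureBuildError(
            "no complete-case rows; check lexicon coverage, speaker metadata "
            f"and parses (drop log: { {k: v for k, v in drop_log.items() if v} })")
    df = pd.DataFrame(rows)
    for col, levels in CATEGORICAL_PREDICTORS.items():
        df[col] = pd.Categorical(df[col], categories=levels)
    for col in PREDICTORS:
        if col not in CATEGORICAL_PREDICTORS and df[col].dtype == object:
            df[col] = df[col].astype(float)
    df.attrs["n_dropped"] = n_dropped
    return df, drop_log


def encode_features(df: pd.DataFrame,
                    predictors: Sequence[str] = None) -> Tuple[np.ndarray, List[str]]:
    """Numeric design matrix for the forest.

    Booleans become 0/1 and categoricals their (alphabetical) level codes;
    CART splits on these codes, so for the three-level categories this is
    an ordinal approximation, documented in the methods note.
    """
    predictors = list(predictors) if predictors is not None else list(PREDICTORS)
    cols = []
    for name in predictors:
        s = df[name]
        if isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.cat.codes.to_numpy(dtype=np.float64))
        else:
            cols.append(s.to_numpy(dtype=np.float64))
    return np.column_stack(cols), predictors
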