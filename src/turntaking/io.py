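"""Readers and writers for the pipeline's external formats.

Formats:

* word-token CSV — columns ``conversation_id, speaker_id, orth, start_ms,
  end_ms, pos, lemma, dialog_act, laughter, n_syllables`` (UTF-8, ``""`` =
  absent);
* Praat TextGrid (long or short dialect), one interval tier per speaker;
* bracketed parse file — one S-expression per line, keyed by
  ``conversation_id<TAB>turn_index<TAB>tree``;
* lexicon CSV — ``lemma, pos, frequency, concreteness, surprisal,
  contextual_diversity``;
* unit-stats CSV — ``unit, mean_ms, sd_ms`` (expected durations for the
  speech-rate measure).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import pandas as pd

from .types import (FormatError, LexiconEntry, SpeakerMeta, ValidationError,
                    WordToken, validate_no_overlap)
from .trees import TreeNode, parse_bracketed_tree, tree_to_string

__all__ = [
    "read_token_table", "write_token_table",
    "read_textgrid", "write_textgrid",
    "read_parse_file", "write_parse_file",
    "read_lexicon", "write_lexicon",
    "read_unit_stats", "write_unit_stats",
    "read_speaker_table", "write_speaker_table",
]

TOKEN_COLUMNS = ["conversation_id", "speaker_id", "orth", "start_ms", "end_ms",
                 "pos", "lemma", "dialog_act", "laughter", "n_syllables"]
_REQUIRED = ["speaker_id", "orth", "start_ms", "end_ms"]


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return str(v)


def read_token_table(path: Union[str, Path]) -> Dict[str, List[WordToken]]:
    """Read a word-token CSV, grouped by conversation.

    Tokens are sorted by (conversation, speaker, start_ms) and validated:
    tokens of one speaker in one conversation must not overlap in time.
    """
    df = pd.read_csv(path, dtype={"conversation_id": str, "speaker_id": str,
                                  "orth": str, "pos": str, "lemma": str,
                                  "dialog_act": str}, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "conversation_id" not in df.columns:
        df["conversation_id"] = "conv0"
    out: Dict[str, List[WordToken]] = {}
    df = df.sort_values(["conversation_id", "speaker_id", "start_ms"],
                        kind="stable")
    for conv, sub in df.groupby("conversation_id", sort=True):
        tokens: List[WordToken] = []
        for row in sub.itertuples(index=False):
            d = row._asdict()
            laugh = d.get("laughter")
            if laugh is None or (isinstance(laugh, float) and pd.isna(laugh)):
                laugh = False
            elif isinstance(laugh, str):
                laugh = laugh.strip().lower() in ("1", "true", "yes", "y")
            else:
                laugh = bool(laugh)
            syl = d.get("n_syllables")
            syl = None if syl is None or pd.isna(syl) else int(syl)
            tokens.append(WordToken(
                conversation_id=str(conv),
                speaker_id=str(d["speaker_id"]),
                orth=str(d["orth"]),
                start_ms=float(d["start_ms"]),
                end_ms=float(d["end_ms"]),
                pos=_opt_str(d.get("pos")),
                lemma=_opt_str(d.get("lemma")),
                dialog_act=_opt_str(d.get("dialog_act")),
                laughter=laugh,
                n_syllables=syl,
            ))
        for spk in sorted({t.speaker_id for t in tokens}):
            validate_no_overlap([t for t in tokens if t.speaker_id == spk])
        out[str(conv)] = tokens
    return out


def write_token_table(tokens: Union[Dict[str, List[WordToken]], List[WordToken]],
                      path: Union[str, Path]) -> None:
    """Inverse of :func:`read_token_table` (field-for-field round trip)."""
    if isinstance(tokens, dict):
        flat = [t for conv in sorted(tokens) for t in tokens[conv]]
    else:
        flat = list(tokens)
    rows = []
    for t in flat:
        rows.append({
            "conversation_id": t.conversation_id, "speaker_id": t.speaker_id,
            "orth": t.orth, "start_ms": t.start_ms, "end_ms": t.end_ms,
            "pos": t.pos or "", "lemma": t.lemma or "",
            "dialog_act": t.dialog_act or "",
            "laughter": int(t.laughter),
            "n_syllables": "" if t.n_syllables is None else t.n_syllables,
        })
    pd.DataFrame(rows, columns=TOKEN_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.17g")


# ---------------------------------------------------------------------------
# Praat TextGrid (hand-rolled: both the long and the short dialect)
# ---------------------------------------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"


def _textgrid_tiers(text: str) -> Dict[str, List[Tuple[float, float, str]]]:
    """Return {tier_name: [(xmin_s, xmax_s, label), ...]} for interval tiers."""
    tiers: Dict[str, List[Tuple[float, float, str]]] = {}
    if re.search(r'item\s*\[', text):  # long format
        chunks = re.split(r'item\s*\[\d+\]\s*:', text)[1:]
        for chunk in chunks:
            cls = re.search(r'class\s*=\s*"([^"]*)"', chunk)
            name = re.search(r'name\s*=\s*"([^"]*)"', chunk)
            if not cls or cls.group(1) != "IntervalTier" or not name:
                continue
            ivals = []
            for m in re.finditer(
                    rf'xmin\s*=\s*({_NUM})\s*xmax\s*=\s*({_NUM})\s*'
                    rf'text\s*=\s*"((?:[^"]|"")*)"', chunk):
                ivals.append((float(m.group(1)), float(m.group(2)),
                              m.group(3).replace('""', '"')))
            tiers[name.group(1)] = ivals
    else:  # short format: "IntervalTier" "name" xmin xmax n then triples
        toks = re.findall(rf'"(?:[^"]|"")*"|{_NUM}', text)
        i = 0
        while i < len(toks):
            if toks[i] == '"IntervalTier"':
                name = toks[i + 1].strip('"')
                n = int(float(toks[i + 4]))
                i += 5
                ivals = []
                for _ in range(n):
                    xmin, xmax = float(toks[i]), float(toks[i + 1])
                    label = toks[i + 2].strip('"').replace('""', '"')
                    ivals.append((xmin, xmax, label))
                    i += 3
                tiers[name] = ivals
            else:
                i += 1
    return tiers


def read_textgrid(path: Union[str, Path], tier_to_speaker: Mapping[str, str],
                  conversation_id: str = "conv0") -> List[WordToken]:
    """Read word tokens from a Praat TextGrid's interval tiers.

    ``tier_to_speaker`` maps tier names to speaker ids; times (TextGrid
    seconds) are converted to milliseconds. Empty-label intervals are
    silence and skipped; a label containing ``[laughter`` yields a token
    with ``laughter=True``.
    """
    text = Path(path).read_text(encoding="utf-8")
    tiers = _textgrid_tiers(text)
    tokens: List[WordToken] = []
    for tier_name, speaker in tier_to_speaker.items():
        if tier_name not in tiers:
            raise FormatError(
                f"{path}: tier {tier_name!r} not found; available: {sorted(tiers)}")
        for xmin, xmax, label in tiers[tier_name]:
            label = label.strip()
            if not label:
                continue
            tokens.append(WordToken(
                conversation_id=conversation_id, speaker_id=speaker,
                orth=label, start_ms=xmin * 1000.0, end_ms=xmax * 1000.0,
                laughter="[laughter" in label.lower(),
            ))
    tokens.sort(key=lambda t: (t.speaker_id, t.start_ms))
    for spk in sorted({t.speaker_id for t in tokens}):
        validate_no_overlap([t for t in tokens if t.speaker_id == spk])
    return tokens


def write_textgrid(tokens: List[WordToken], path: Union[str, Path],
                   speaker_to_tier: Optional[Mapping[str, str]] = None) -> None:
    """Write tokens as a long-format TextGrid, one interval tier per speaker.

    Gaps between tokens become empty (silence) intervals.
    """
    speakers = sorted({t.speaker_id for t in tokens})
    speaker_to_tier = speaker_to_tier or {s: s for s in speakers}
    xmax = max((t.end_ms for t in tokens), default=0.0) / 1000.0
    lines = ['File type = "ooTextFile"', 'Object class = "TextGrid"', '',
             'xmin = 0', f'xmax = {xmax}', 'tiers? <exists>',
             f'size = {len(speakers)}', 'item []:']
    for i, spk in enumerate(speakers, 1):
        toks = sorted([t for t in tokens if t.speaker_id == spk],
                      key=lambda t: t.start_ms)
        ivals: List[Tuple[float, float, str]] = []
        cursor = 0.0
        for t in toks:
            s, e = t.start_ms / 1000.0, t.end_ms / 1000.0
            if s > cursor:
                ivals.append((cursor, s, ""))
            label = t.orth
            if t.laughter and "[laughter" not in label.lower():
                label = f"{label} [laughter]"
            ivals.append((s, e, label))
            cursor = e
        if cursor < xmax:
            ivals.append((cursor, xmax, ""))
        lines += [f'    item [{i}]:', '        class = "IntervalTier"',
                  f'        name = "{speaker_to_tier[spk]}"',
                  '        xmin = 0', f'        xmax = {xmax}',
                  f'        intervals: size = {len(ivals)}']
        for j, (a, b, lab) in enumerate(ivals, 1):
            lines += [f'        intervals [{j}]:', f'            xmin = {a}',
                      f'            xmax = {b}',
                      f'            text = "{lab.replace(chr(34), chr(34) * 2)}"']
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Parse trees, lexicon, unit stats, speaker metadata
# ---------------------------------------------------------------------------

def read_parse_file(path: Union[str, Path]) -> Dict[Tuple[str, int], List[TreeNode]]:
    """Read ``conversation_id<TAB>turn_index<TAB>bracketed-tree`` lines.

    A (conversation, turn) key may repeat; its trees accumulate in order.
    """
    out: Dict[Tuple[str, int], List[TreeNode]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            conv, idx, tree_text = line.split("\t", 2)
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields") from e
        out.setdefault((conv, int(idx)), []).append(parse_bracketed_tree(tree_text))
    return out


def write_parse_file(parses: Mapping[Tuple[str, int], List[TreeNode]],
                     path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (conv, idx) in sorted(parses):
            for tree in parses[(conv, idx)]:
                fh.write(f"{conv}\t{idx}\t{tree_to_string(tree)}\n")


def read_lexicon(path: Union[str, Path]) -> Dict[Tuple[str, str], LexiconEntry]:
    """Lexicon CSV → {(lemma, pos): LexiconEntry}; (lemma, pos) must be unique."""
    df = pd.read_csv(path, dtype={"lemma": str, "pos": str},
                     float_precision="round_trip")
    out: Dict[Tuple[str, str], LexiconEntry] = {}
    for row in df.itertuples(index=False):
        key = (row.lemma, row.pos)
        if key in out:
            raise ValidationError(f"{path}: duplicate lexicon key {key}")
        out[key] = LexiconEntry(
            lemma=row.lemma, pos=row.pos, frequency=float(row.frequency),
            concreteness=None if pd.isna(row.concreteness) else float(row.concreteness),
            surprisal=None if pd.isna(row.surprisal) else float(row.surprisal),
            contextual_diversity=(None if pd.isna(row.contextual_diversity)
                                  else float(row.contextual_diversity)),
        )
    return out


def write_lexicon(lexicon: Mapping[Tuple[str, str], LexiconEntry],
                  path: Union[str, Path]) -> None:
    rows = [{"lemma": e.lemma, "pos": e.pos, "frequency": e.frequency,
             "concreteness": e.concreteness, "surprisal": e.surprisal,
             "contextual_diversity": e.contextual_diversity}
            for e in lexicon.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_unit_stats(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit": str},
                     float_precision="round_trip")
    for col in ("unit", "mean_ms"):
        if col not in df.columns:
            raise FormatError(f"{path}: unit-stats CSV needs columns unit, mean_ms")
    return df


def write_unit_stats(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)


def read_speaker_table(path: Union[str, Path]) -> Dict[str, SpeakerMeta]:
    df = pd.read_csv(path, dtype=str)
    return {r.speaker_id: SpeakerMeta(r.speaker_id, r.sex)
            for r in df.itertuples(index=False)}


def write_speaker_table(speakers: Mapping[str, SpeakerMeta],
                        path: Union[str, Path]) -> None:
    rows = [{"speaker_id": s.speaker_id, "sex": s.sex} for s in speakers.values()]
    pd.DataFrame(rows).to_csv(path, index=False)
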