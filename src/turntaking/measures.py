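"""Per-turn processing measures.

Nine predictors per turn: duration, speech-rate delta (normalized
departure from the expected duration; positive = slower than expected),
mean log frequency, mean concreteness, mean surprisal, information
uniformity (mean absolute deviation of word surprisal from the turn mean —
0 when information is perfectly evenly distributed), mean contextual
diversity, syntactic tree height, and clause count.

Lexical measures are looked up per (lemma, coarse POS) in a lexicon table
and averaged over the words with lexicon hits; the number of covered words
is tracked so downstream analyses can enforce complete cases.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd

from .trees import count_clauses, tree_height
from .types import LexiconEntry, Turn, WordToken

__all__ = ["ProcessingProfile", "lemmatize", "coarse_pos",
           "build_frequency_lexicon", "turn_profile", "speech_rate_delta",
           "unit_stats_from_tokens"]

_VOWELS = "aeiou"
_WORD = re.compile(r"[^\w']+")


_POS_FAMILIES = ("NN", "VB", "JJ", "RB", "PRP", "WP")


def coarse_pos(pos: Optional[str]) -> str:
    """Collapse a Penn tag to its coarse class (NNS → NN, VBD → VB,
    PRP$ → PRP, ...); tags outside the inflecting families pass through."""
    if not pos:
        return ""
    tag = pos.upper()
    for fam in _POS_FAMILIES:
        if tag.startswith(fam):
            return fam
    return tag


def _strip_plural(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ses", "xes", "zes", "ches", "shes")) and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        return word[:-1]
    return word


def _undouble(stem: str) -> str:
    # "runn" -> "run"; keep "ll"/"ss" endings intact ("telling" -> "tell")
    if (len(stem) > 2 and stem[-1] == stem[-2]
            and stem[-1] not in _VOWELS + "ls"):
        return stem[:-1]
    return stem


def _restore_e(stem: str) -> str:
    # "mak" -> "make": consonant-vowel-consonant with a non-glide final
    if (len(stem) > 2 and stem[-1] not in _VOWELS + "wxy"
            and stem[-2] in _VOWELS and stem[-3] not in _VOWELS):
        return stem + "e"
    return stem


def _undouble_or_restore(stem: str) -> str:
    # doubled final consonant ("runn") blocks e-restoration ("run", not
    # "rune"); otherwise try CVC e-restoration ("mak" -> "make")
    undoubled = _undouble(stem)
    return undoubled if undoubled != stem else _restore_e(stem)


def _strip_verb(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ing") and len(word) > 4:
        return _undouble_or_restore(word[:-3])
    if word.endswith("ed") and len(word) > 3:
        return _undouble_or_restore(word[:-2])
    if word.endswith("es") and len(word) > 3:
        return word[:-2] if word.endswith(("ses", "xes", "zes", "ches", "shes")) \
            else word[:-1]
    if word.endswith("s") and not word.endswith("ss") and len(word) > 2:
        return word[:-1]
    return word


def lemmatize(orth: str, pos: Optional[str]) -> str:
    """Rule-based de-inflection: plural -s/-es on nouns, tense/number
    -s/-ed/-ing on verbs (with consonant-undoubling and e-restoration
    heuristics); other classes pass through lower-cased."""
    word = _WORD.sub("", orth.lower())
    if pos == "NNS":
        return _strip_plural(word)
    if pos in ("VBZ", "VBD", "VBG", "VBN"):
        return _strip_verb(word)
    return word


def token_lemma(tok: WordToken) -> str:
    """A token's lemma: the explicit field, else rule-based de-inflection."""
    return tok.lemma if tok.lemma else lemmatize(tok.orth, tok.pos)


@dataclass
class ProcessingProfile:
    """The nine processing measures for one turn (plus coverage counts).

    Lexical fields are ``None`` when no word of the turn had a lexicon
    hit; syntactic fields are ``None`` when the turn has no parse.
    """

    duration_ms: float
    n_words: int
    n_syllables: Optional[int]
    rate_delta: Optional[float]
    mean_log_frequency: Optional[float]
    mean_concreteness: Optional[float]
    mean_surprisal: Optional[float]
    info_uniformity: Optional[float]
    mean_contextual_diversity: Optional[float]
    tree_height: Optional[int]
    n_clauses: Optional[int]
    n_covered_words: int = 0


def build_frequency_lexicon(tokens_by_conv: Mapping[str, Iterable[WordToken]],
                            ) -> Dict[Tuple[str, str], LexiconEntry]:
    """Corpus-internal frequency lexicon.

    Counts each (lemma, coarse POS) after de-inflection across the whole
    corpus; contextual diversity is the number of distinct conversations
    containing the pair. Concreteness/surprisal are left unset (those come
    from external ratings/estimates).
    """
    freq: Dict[Tuple[str, str], int] = {}
    convs: Dict[Tuple[str, str], set] = {}
    for conv, toks in tokens_by_conv.items():
        for t in toks:
            key = (token_lemma(t), coarse_pos(t.pos))
            freq[key] = freq.get(key, 0) + 1
            convs.setdefault(key, set()).add(conv)
    return {k: LexiconEntry(lemma=k[0], pos=k[1], frequency=v,
                            contextual_diversity=len(convs[k]))
            for k, v in freq.items()}


def _mean(xs) -> Optional[float]:
    xs = [x for x in xs if x is not None]
    return sum(xs) / len(xs) if xs else None


def turn_profile(turn: Turn,
                 lexicon: Mapping[Tuple[str, str], LexiconEntry],
                 unit_stats: Optional[pd.DataFrame] = None,
                 total_tokens: Optional[float] = None,
                 log_frequency: bool = True) -> ProcessingProfile:
    """Compute the processing profile of one turn.

    ``total_tokens`` sets the per-million scaling of log frequency
    (default: the lexicon's summed counts). ``log_frequency=False`` means
    raw counts instead of ln(frequency-per-million + 1).
    """
    if not lexicon:
        raise ValueError("turn_profile needs a non-empty lexicon")
    if total_tokens is None:
        total_tokens = sum(e.frequency for e in lexicon.values())
    hits = []
    for tok in turn.tokens:
        e = lexicon.get((token_lemma(tok), coarse_pos(tok.pos)))
        if e is not None:
            hits.append(e)
    surprisals = [e.surprisal for e in hits if e.surprisal is not None]
    info_unif = None
    if surprisals:
        sbar = sum(surprisals) / len(surprisals)
        info_unif = sum(abs(s - sbar) for s in surprisals) / len(surprisals)
    if log_frequency:
        freqs = [math.log(e.frequency / total_tokens * 1e6 + 1.0) for e in hits]
    else:
        freqs = [e.frequency for e in hits]
    syls = [t.n_syllables for t in turn.tokens]
    heights = [tree_height(p) for p in turn.parses]
    return ProcessingProfile(
        duration_ms=turn.duration_ms,
        n_words=len(turn.tokens),
        n_syllables=sum(syls) if all(s is not None for s in syls) else None,
        rate_delta=(speech_rate_delta(turn, unit_stats)
                    if unit_stats is not None else None),
        mean_log_frequency=_mean(freqs),
        mean_concreteness=_mean(e.concreteness for e in hits),
        mean_surprisal=_mean(surprisals),
        info_uniformity=info_unif,
        mean_contextual_diversity=_mean(e.contextual_diversity for e in hits),
        tree_height=max(heights) if heights else None,
        n_clauses=sum(count_clauses(p) for p in turn.parses) if turn.parses else None,
        n_covered_words=len(hits),
    )


def unit_stats_from_tokens(tokens: Iterable[WordToken],
                           level: str = "word") -> pd.DataFrame:
    """Mean/SD observed duration per unit (the expected-duration table)."""
    rows = []
    for t in tokens:
        unit = t.orth.lower() if level == "word" else None
        if level == "syllable":
            if not t.n_syllables:
                continue
            rows.append({"unit": "syllable",
                         "dur": t.duration_ms / t.n_syllables})
        else:
            rows.append({"unit": unit, "dur": t.duration_ms})
    df = pd.DataFrame(rows)
    g = df.groupby("unit")["dur"].agg(["mean", "std"]).reset_index()
    return g.rename(columns={"mean": "mean_ms", "std": "sd_ms"})


def speech_rate_delta(turn: Turn, unit_stats: pd.DataFrame,
                      level: str = "word") -> float:
    """Normalized departure from the expected duration.

    ``(observed − expected) / expected`` where observed is the summed token
    duration and expected the summed corpus mean duration of the turn's
    units (words by default; ``syllable`` uses a per-syllable mean times
    the turn's syllable count). Units absent from the table fall back to
    the table's global mean. Positive values mean slower-than-expected
    speech.
    """
    if unit_stats is None or len(unit_stats) == 0:
        raise ValueError("speech_rate_delta needs a non-empty unit-stats table")
    means = dict(zip(unit_stats["unit"].astype(str), unit_stats["mean_ms"]))
    global_mean = float(unit_stats["mean_ms"].mean())
    observed = sum(t.duration_ms for t in turn.tokens)
    if level == "word":
        expected = sum(means.get(t.orth.lower(), global_mean)
                       for t in turn.tokens)
    elif level == "syllable":
        per_syl = means.get("syllable", global_mean)
        n = sum(t.n_syllables or 1 for t in turn.tokens)
        expected = per_syl * n
    else:
        raise ValueError(f"unknown rate level {level!r}")
    return (observed - expected) / expected
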