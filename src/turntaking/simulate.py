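"""Synthetic dyadic conversations with known turn-taking structure.

The generator emulates the statistical shape of a Switchboard-style
telephone corpus: two strangers talk for about five minutes, producing on
average 12 floor transfers per minute. Dialog acts follow a Markov chain
over the NXT inventory in which an initiating act (e.g. a yes/no
question) up-weights its expected next acts, so adjacency pairs arise
naturally. Every floor transfer's FTO is drawn from a distribution whose
mean depends on the sequence type of the transfer — the four
initiating/responding combinations carry the corpus-estimated means
(init→resp 200.7 ms, resp→init 284.8 ms, init→init 298 ms, resp→resp
157 ms) — plus injectable covariate effects (speaker sex, T1 speech rate,
laughter), and word timings are laid out so that re-running the turn
gluing and FTO extraction recovers the drawn values exactly. Ground truth
(sequence type, drawn FTO, injected effects) is exported per transfer for
parameter-recovery tests.

Covariate effects are mean-centered (sex: ±half the per-male effect) so
that the sequence-type group means stay at their configured values;
invited laughter (laughter in both turns) instead *replaces* the mean
with its own group mean, which is how the source statistic is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .coding import ActScheme, default_scheme
from .trees import TreeNode
from .types import LexiconEntry, SpeakerMeta, WordToken

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate_lexicon",
           "generate_conversation", "generate_corpus", "sequence_type",
           "DEFAULT_FTO_MEANS", "DEFAULT_ACT_WEIGHTS"]

DEFAULT_FTO_MEANS = {
    "init_resp": 200.7,
    "resp_init": 284.8,
    "init_init": 298.0,
    "resp_resp": 157.0,
}

# Plausible Switchboard-like marginal act frequencies (statements and
# backchannels dominate); acts not listed get a small floor weight.
DEFAULT_ACT_WEIGHTS = {
    "statement": 0.32, "opinion": 0.12, "backchannel": 0.14,
    "acknowledge": 0.05, "agree": 0.05, "yes": 0.03, "affirm": 0.02,
    "no": 0.012, "neg": 0.008, "answer": 0.025, "apprec": 0.02,
    "yn-q": 0.03, "wh-q": 0.015, "decl-q": 0.008, "yn-decl-q": 0.008,
    "open-q": 0.005, "tag-q": 0.005, "or": 0.004, "repeat-q": 0.004,
    "sum": 0.008, "hedge": 0.01, "maybe": 0.006, "reject": 0.004,
    "ans-dispref": 0.004, "abandon": 0.015, "hold": 0.006, "commit": 0.006,
    "directive": 0.006, "quote": 0.008, "completion": 0.004,
    "backchannel-q": 0.008, "other": 0.01, "uninterp": 0.006,
}

# Mean word counts per act before global calibration (short response
# tokens vs. long statements, echoing the corpus pattern that most turns
# under 700 ms are backchannels or agreements).
_BASE_WORD_COUNTS = {
    "backchannel": 1.3, "backchannel-q": 1.5, "acknowledge": 1.6,
    "yes": 1.3, "no": 1.3, "affirm": 1.6, "neg": 2.0, "agree": 1.8,
    "apprec": 1.8, "answer": 4.0, "hedge": 3.0, "maybe": 2.5,
    "reject": 3.0, "ans-dispref": 3.5, "abandon": 2.5, "hold": 1.5,
    "uninterp": 1.5, "statement": 14.0, "opinion": 14.0, "quote": 8.0,
    "yn-q": 7.0, "wh-q": 6.0, "decl-q": 6.0, "yn-decl-q": 6.0,
    "open-q": 5.0, "tag-q": 4.0, "or": 4.0, "repeat-q": 3.0, "sum": 8.0,
    "commit": 6.0, "directive": 5.0, "completion": 3.0, "other": 4.0,
}
_PLACEHOLDERS = ["uh", "um", "well"]
_CONTENT_POS = ["NN", "VB", "JJ", "RB", "PRP", "DT", "IN"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults are the corpus-estimated values: ~5-minute conversations, 12
    floor transfers per minute, sequence-type FTO means of
    200.7/284.8/298/157 ms with SD 448 ms, −142 ms mean under invited
    laughter, +70 ms per male speaker, and ~35% of T1 backchannels
    overlapped (implied by the resp→resp mean and SD, recorded here as a
    validation target rather than a separate mechanism).
    """

    n_conversations: int = 1
    target_duration_ms: float = 300_000.0
    transfers_per_min: float = 12.0
    fto_means_by_type: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FTO_MEANS))
    fto_mean_other: float = 187.0
    fto_sd: float = 448.0
    fto_noise: str = "normal"  # or "lognormal" (right-skewed, same mean/SD)
    laughter_both_mean: float = -142.0
    laughter_single_offset: float = -60.0
    male_effect_ms: float = 70.0
    backchannel_overlap_prob: float = 0.35
    rate_slope_ms: float = -262.0
    rate_sd: float = 0.15
    placeholder_prob: float = 0.2
    placeholder_max: int = 2
    all_placeholder_prob: float = 0.01
    laughter_base_prob: float = 0.03
    laughter_invite_prob: float = 0.3
    adjacency_bias: float = 0.6
    repair_prob: float = 0.06
    response_continuation_bias: float = 0.35
    second_act_prob: float = 0.15
    act_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACT_WEIGHTS))
    lexicon_size: int = 2000
    zipf_exponent: float = 1.0
    max_gap_ms: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.act_weights.items():
            if v < 0:
                raise ValueError(f"negative act weight for {k}")
        for p in (self.placeholder_prob, self.all_placeholder_prob,
                  self.laughter_base_prob, self.laughter_invite_prob,
                  self.adjacency_bias, self.second_act_prob,
                  self.repair_prob, self.response_continuation_bias,
                  self.backchannel_overlap_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def zeroed_effects(self) -> "GeneratorConfig":
        """A null copy: one FTO mean for every transfer, no covariate
        effects — FTO independent of all predictors."""
        return replace(
            self,
            fto_means_by_type={k: self.fto_mean_other
                               for k in self.fto_means_by_type},
            laughter_both_mean=self.fto_mean_other,
            laughter_single_offset=0.0,
            male_effect_ms=0.0,
            rate_slope_ms=0.0,
        )


@dataclass
class SyntheticCorpus:
    tokens_by_conv: Dict[str, List[WordToken]]
    parses: Dict[Tuple[str, int], List[TreeNode]]
    lexicon: Dict[Tuple[str, str], LexiconEntry]
    unit_stats: pd.DataFrame
    speakers: Dict[str, SpeakerMeta]
    ground_truth: pd.DataFrame
    config: GeneratorConfig


def sequence_type(t1_act: str, t2_act: str, scheme: ActScheme) -> str:
    """The transfer's sequence type from T1's (final) and T2's (first) act."""
    r1, r2 = scheme[t1_act], scheme[t2_act]
    if r1.initiating and r2.responding:
        return "init_resp"
    if r1.responding and r2.initiating:
        return "resp_init"
    if r1.initiating and r2.initiating:
        return "init_init"
    if r1.responding and r2.responding:
        return "resp_resp"
    return "other"


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

def generate_lexicon(config: GeneratorConfig,
                     seed: Optional[int] = None,
                     ) -> Tuple[Dict[Tuple[str, str], LexiconEntry],
                                pd.DataFrame, pd.DataFrame]:
    """Zipf-frequency lexicon plus the word-level expected-duration table.

    Returns ``(lexicon, unit_stats, word_table)``; ``word_table`` carries
    per-word sampling probability, syllable count and expected duration
    used by the conversation generator.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.lexicon_size
    ranks = np.arange(1, n + 1, dtype=float)
    probs = ranks ** (-config.zipf_exponent)
    probs /= probs.sum()
    words = [f"w{i:05d}" for i in range(n)]
    pos = [(_CONTENT_POS[i % len(_CONTENT_POS)]) for i in range(n)]
    syllables = 1 + rng.poisson(0.8, size=n).clip(0, 4)
    concreteness = rng.uniform(1.0, 5.0, size=n)
    surprisal = rng.gamma(8.0, 1.25, size=n)  # bits-scale, mean 10
    frequency = np.maximum(1, np.round(probs * 1e6)).astype(float)
    diversity = np.maximum(1, np.minimum(
        max(config.n_conversations, 1),
        np.round(np.sqrt(frequency)))).astype(float)
    exp_dur = 100.0 + 95.0 * syllables

    lexicon: Dict[Tuple[str, str], LexiconEntry] = {}
    rows = []
    for i, w in enumerate(words):
        lexicon[(w, pos[i])] = LexiconEntry(
            lemma=w, pos=pos[i], frequency=frequency[i],
            concreteness=float(concreteness[i]),
            surprisal=float(surprisal[i]),
            contextual_diversity=float(diversity[i]))
        rows.append({"word": w, "pos": pos[i], "prob": probs[i],
                     "n_syllables": int(syllables[i]),
                     "expected_ms": float(exp_dur[i])})
    for ph in _PLACEHOLDERS:
        lexicon[(ph, "UH")] = LexiconEntry(
            lemma=ph, pos="UH", frequency=2e4, concreteness=1.2,
            surprisal=2.0, contextual_diversity=float(
                max(config.n_conversations, 1)))
    word_table = pd.DataFrame(rows)
    unit_stats = pd.DataFrame({
        "unit": words + _PLACEHOLDERS,
        "mean_ms": list(exp_dur) + [250.0, 280.0, 260.0],
        "sd_ms": [40.0] * (n + 3),
    })
    return lexicon, unit_stats, word_table


# ---------------------------------------------------------------------------
# Parses
# ---------------------------------------------------------------------------

def _make_parse(orths: List[str], pos: List[str], n_clauses: int) -> TreeNode:
    """Right-branching template: ``n_clauses`` nested S nodes (0 for a
    response-token INTJ fragment), words as preterminal leaves."""
    def preterminals(ws, ps):
        return [TreeNode(p or "XX", [w]) for w, p in zip(ws, ps)]

    if n_clauses <= 0:
        return TreeNode("INTJ", preterminals(orths, pos))
    chunks = np.array_split(np.arange(len(orths)), min(n_clauses, max(len(orths), 1)))
    chunks = [c for c in chunks if len(c)] or [np.array([], dtype=int)]
    tree: Optional[TreeNode] = None
    for c in reversed(chunks):
        kids = preterminals([orths[i] for i in c], [pos[i] for i in c])
        if tree is not None:
            kids.append(tree)
        tree = TreeNode("S", kids)
    # pad clause count if fewer chunks than requested
    extra = n_clauses - sum(1 for _ in chunks)
    for _ in range(extra):
        tree = TreeNode("S", [tree])
    return tree


def _act_clauses(act: str, n_words: int, scheme: ActScheme) -> int:
    if scheme[act].response_token:
        return 0
    if act in ("statement", "opinion", "quote", "sum"):
        return 1 + n_words // 8
    return 1


# ---------------------------------------------------------------------------
# Conversation
# ---------------------------------------------------------------------------

def _act_sampler(config: GeneratorConfig, scheme: ActScheme):
    acts = list(scheme.acts)
    w = np.array([config.act_weights.get(a, 0.001) for a in acts])
    w /= w.sum()
    index = {a: i for i, a in enumerate(acts)}
    return acts, w, index


def act_chain(config: GeneratorConfig, scheme: ActScheme
              ) -> Tuple[List[str], np.ndarray, np.ndarray, np.ndarray]:
    """The act-to-act Markov chain the generator follows.

    Returns ``(acts, marginal, T, stationary)`` where ``T[i, j]`` is the
    probability that a turn whose previous turn ended in act i starts with
    act j (repair initiation, expected-next up-weighting, and the marginal
    fallback combined), and ``stationary`` is T's stationary distribution.
    """
    acts, marginal, _ = _act_sampler(config, scheme)
    n = len(acts)
    T = np.tile(marginal, (n, 1))
    repair_j = acts.index("repeat-q") if "repeat-q" in acts else None
    resp_idx = [i for i, a in enumerate(acts) if scheme[a].responding]
    resp_marginal = np.zeros(n)
    resp_marginal[resp_idx] = marginal[resp_idx] / marginal[resp_idx].sum()
    for i, a in enumerate(acts):
        row = marginal.copy()
        if scheme[a].initiating:
            expected = sorted(x for x in scheme[a].expected_next if x in scheme)
            if expected:
                wts = np.array([config.act_weights.get(x, 0.001)
                                for x in expected])
                wts /= wts.sum()
                row = (1 - config.adjacency_bias) * marginal
                for x, w in zip(expected, wts):
                    row[acts.index(x)] += config.adjacency_bias * w
            if repair_j is not None:
                row = (1 - config.repair_prob) * row
                row[repair_j] += config.repair_prob
        elif scheme[a].responding:
            row = ((1 - config.response_continuation_bias) * marginal
                   + config.response_continuation_bias * resp_marginal)
        T[i] = row
    pi = marginal.copy()
    for _ in range(500):
        nxt = pi @ T
        if np.abs(nxt - pi).max() < 1e-12:
            pi = nxt
            break
        pi = nxt
    return acts, marginal, T, pi


def _expected_fto_mean(config: GeneratorConfig, scheme: ActScheme,
                       acts: List[str], T: np.ndarray,
                       pi: np.ndarray) -> float:
    m = 0.0
    for i, a in enumerate(acts):
        for j, b in enumerate(acts):
            st = sequence_type(a, b, scheme)
            m += pi[i] * T[i, j] * config.fto_means_by_type.get(
                st, config.fto_mean_other)
    return m


def _calibrate_word_scale(config: GeneratorConfig, word_table: pd.DataFrame,
                          scheme: ActScheme) -> float:
    """Global multiplier on act word counts so the realized transfer rate
    matches ``transfers_per_min`` (turn cycle = mean turn duration + mean
    FTO), computed against the act chain's stationary distribution."""
    acts, _, T, pi = act_chain(config, scheme)
    e_word = float((word_table["prob"] * word_table["expected_ms"]).sum())
    e_word *= math.exp(0.25 ** 2 / 2)  # log-normal duration jitter mean
    e_gap = 90.0
    mean_fto = _expected_fto_mean(config, scheme, acts, T, pi)
    target_turn = 60_000.0 / config.transfers_per_min - mean_fto
    base_wc = np.array([_BASE_WORD_COUNTS.get(a, 4.0) for a in acts])
    mean_wc = float((pi * base_wc).sum())
    return max(0.1, (target_turn + e_gap) / (mean_wc * (e_word + e_gap)))


def _draw_fto(rng: np.random.Generator, mean: float, sd: float,
              noise: str) -> float:
    if noise == "normal" or sd == 0:
        return float(rng.normal(mean, sd))
    if noise == "lognormal":
        sigma = 0.6
        scale = sd / (math.exp(sigma ** 2 / 2)
                      * math.sqrt(math.exp(sigma ** 2) - 1))
        return float(mean + scale * (rng.lognormal(0.0, sigma)
                                     - math.exp(sigma ** 2 / 2)))
    raise ValueError(f"unknown fto_noise {noise!r}")


def generate_conversation(config: GeneratorConfig, conv_id: str,
                          rng: np.random.Generator,
                          lexicon_bundle=None, scheme: Optional[ActScheme] = None):
    """Generate one conversation.

    Returns ``(tokens, parses, ground_truth_rows, speakers)``. Word
    timings realize each drawn FTO exactly. Feasibility (turn onsets must
    be ordered, and a speaker's consecutive turns must stay more than the
    gluing gap apart) is secured BEFORE each FTO is drawn: every turn is
    planned (acts, laughter, words) one step ahead, the minimum feasible
    span of the current turn is computed from the intended FTO means of
    the flanking transfers, the turn is pre-extended with filler words if
    needed (logged), and the FTO is then drawn from a normal truncated
    symmetrically about its intended mean. Pre-extension therefore never
    correlates with any FTO residual, and every group mean stays exactly
    at its configured value.
    """
    scheme = scheme or default_scheme()
    if lexicon_bundle is None:
        lexicon_bundle = generate_lexicon(config, seed=config.seed)
    _, _, word_table = lexicon_bundle
    acts, act_probs, _ = _act_sampler(config, scheme)
    wc_scale = _calibrate_word_scale(config, word_table, scheme)

    words = word_table["word"].to_numpy()
    wpos = word_table["pos"].to_numpy()
    wprob = word_table["prob"].to_numpy()
    wsyl = word_table["n_syllables"].to_numpy()
    wexp = word_table["expected_ms"].to_numpy()
    ph_base = {"uh": 250.0, "um": 280.0, "well": 260.0}

    spk_ids = [f"{conv_id}-A", f"{conv_id}-B"]
    sexes = ["male" if rng.random() < 0.5 else "female" for _ in spk_ids]
    rates = np.clip(rng.normal(1.0, config.rate_sd, size=2), 0.7, 1.4)
    speakers = {sid: SpeakerMeta(sid, sx) for sid, sx in zip(spk_ids, sexes)}

    def plan_turn(prev_last_act, prev_laughter, is_first):
        """Draw a turn's acts, words, placeholders and laughter."""
        prev_rec = scheme[prev_last_act] if prev_last_act is not None else None
        expected: List[str] = []
        if prev_rec is not None and prev_rec.initiating:
            if "repeat-q" in scheme and rng.random() < config.repair_prob:
                # other-initiated repair: a question answered with a
                # signal of non-understanding (an initiating act itself)
                expected = ["repeat-q"]
            elif rng.random() < config.adjacency_bias:
                expected = sorted(a for a in prev_rec.expected_next
                                  if a in scheme)
        elif (prev_rec is not None and prev_rec.responding
                and rng.random() < config.response_continuation_bias):
            # assessment/receipt chains: responses tend to be met with
            # further response tokens
            expected = sorted(a for a in scheme.acts if scheme[a].responding)
        if expected:
            wts = np.array([config.act_weights.get(a, 0.001)
                            for a in expected])
            first_act = str(expected[rng.choice(len(expected),
                                                p=wts / wts.sum())])
        else:
            first_act = str(acts[rng.choice(len(acts), p=act_probs)])
        all_ph = (not is_first) and rng.random() < config.all_placeholder_prob
        if all_ph:
            idx = np.array([], dtype=int)
        else:
            mean_wc = max(1.0,
                          _BASE_WORD_COUNTS.get(first_act, 4.0) * wc_scale)
            idx = rng.choice(len(words), size=int(rng.geometric(1.0 / mean_wc)),
                             p=wprob)
        turn_acts = [first_act]
        # a second act needs at least two content words to attach to
        if len(idx) >= 2 and rng.random() < config.second_act_prob:
            turn_acts.append(str(acts[rng.choice(len(acts), p=act_probs)]))
        n_prefix = 0
        if not is_first and (all_ph
                             or rng.random() < config.placeholder_prob):
            n_prefix = int(rng.integers(1, config.placeholder_max + 1))
        prefix = [_PLACEHOLDERS[int(i)] for i in
                  rng.integers(0, len(_PLACEHOLDERS), size=n_prefix)]
        p_laugh = (config.laughter_invite_prob if prev_laughter
                   else config.laughter_base_prob)
        has_laughter = rng.random() < p_laugh and not all_ph
        return {"first_act": first_act, "turn_acts": turn_acts, "idx": idx,
                "prefix": prefix, "all_ph": all_ph, "laughter": has_laughter,
                "n_prefix": n_prefix}

    def layout_turn(plan, rate):
        """Realize a plan as tokens at offsets relative to the turn onset."""
        toks: List[dict] = []
        cursor = 0.0
        prefix_rel = 0.0
        idx, prefix = plan["idx"], plan["prefix"]
        turn_acts = plan["turn_acts"]
        for j, ph in enumerate(prefix):
            dur = max(30.0, ph_base[ph] * rate
                      * float(rng.lognormal(0.0, 0.25)))
            toks.append({"orth": ph, "pos": "UH", "start": cursor,
                         "end": cursor + dur, "syl": 1, "laughter": False,
                         "idx": -1, "act": turn_acts[0]})
            cursor += dur
            if j < len(prefix) - 1 or idx.size:
                cursor += float(rng.uniform(20, 160))
            # onset of the first non-placeholder word: exactly what
            # placeholder stripping adds to the FTO
            prefix_rel = cursor
        n_content = len(idx)
        for j, i in enumerate(idx):
            dur = max(30.0, wexp[i] * rate * float(rng.lognormal(0.0, 0.25)))
            act = turn_acts[0] if (len(turn_acts) == 1 or j < n_content / 2) \
                else turn_acts[1]
            toks.append({"orth": str(words[i]), "pos": str(wpos[i]),
                         "start": cursor, "end": cursor + dur,
                         "syl": int(wsyl[i]), "laughter": False,
                         "idx": int(i), "act": act})
            cursor += dur
            if j < n_content - 1:
                cursor += float(rng.uniform(20, 160))
        if plan["laughter"] and toks:
            toks[int(rng.integers(0, len(toks)))]["laughter"] = True
        return toks

    def extend_layout(toks, d_min, rate, all_ph):
        """Append filler until the turn spans at least ``d_min`` ms."""
        extended = False
        while toks[-1]["end"] < d_min:
            extended = True
            gap = float(rng.uniform(20, 160))
            if all_ph:
                ph = _PLACEHOLDERS[int(rng.integers(0, len(_PLACEHOLDERS)))]
                orth, posx, syl, i, base = ph, "UH", 1, -1, ph_base[ph]
            else:
                i = int(rng.choice(len(words), p=wprob))
                orth, posx, syl, base = (str(words[i]), str(wpos[i]),
                                         int(wsyl[i]), wexp[i])
            dur = max(30.0, base * rate * float(rng.lognormal(0.0, 0.25)))
            start = toks[-1]["end"] + gap
            toks.append({"orth": orth, "pos": posx, "start": start,
                         "end": start + dur, "syl": syl, "laughter": False,
                         "idx": i, "act": toks[-1]["act"]})
        return extended

    def intended_mean(t1_act, t2_act, l1, l2, t1_slot):
        """Sequence type and intended FTO mean of a transfer."""
        st = sequence_type(t1_act, t2_act, scheme)
        if l1 and l2:
            mean = config.laughter_both_mean
        else:
            mean = config.fto_means_by_type.get(st, config.fto_mean_other)
            if l1 or l2:
                mean += config.laughter_single_offset
        mean += config.male_effect_ms * ((sexes[t1_slot] == "male") - 0.5)
        mean += config.male_effect_ms * ((sexes[1 - t1_slot] == "male") - 0.5)
        mean += config.rate_slope_ms * (rates[t1_slot] - 1.0)
        return st, mean

    tokens: List[WordToken] = []
    parses: Dict[Tuple[str, int], List[TreeNode]] = {}
    gt_rows: List[dict] = []

    turn_tokens_prev: List[dict] = []
    prev_last_act: Optional[str] = None
    prev_laughter = False
    prev_extended = False
    end_prev = 0.0
    onset_prev = -1.0
    end_same: List[float] = [-1e9, -1e9]
    plan = plan_turn(None, False, True)
    mean_k: Optional[float] = None  # intended mean of transfer k-1 -> k
    seq_k: Optional[str] = None
    k = 0
    while end_prev < config.target_duration_ms:
        s = k % 2
        toks_rel = layout_turn(plan, rates[s])

        # plan the NEXT turn now, so this turn's minimum span can respect
        # the next transfer's intended mean before any FTO is drawn
        plan_next = plan_turn(toks_rel[-1]["act"] if toks_rel else
                              plan["turn_acts"][-1], plan["laughter"], False)
        _, mean_next = intended_mean(
            plan["turn_acts"][-1], plan_next["first_act"],
            plan["laughter"], plan_next["laughter"], t1_slot=s)

        # minimum span: the next transfer's symmetric-truncation window
        # must leave at least 1 ms below its intended mean (margin 2 ms);
        # 160 ms floor keeps even one-word turns physically plausible.
        # The skewed option uses one-sided rejection instead and needs no
        # mean-based guard.
        sym = not (config.fto_noise == "lognormal" and config.fto_sd > 0)
        d_min = 160.0
        if sym:
            d_min = max(d_min, 3.0 - mean_next)
            if k > 0 and mean_k is not None:
                d_min = max(d_min, 184.0 - mean_k - mean_next)
        self_extended = extend_layout(toks_rel, d_min, rates[s],
                                      plan["all_ph"])
        d_k = toks_rel[-1]["end"]

        # --- draw the FTO ---
        if k == 0:
            fto = float(rng.uniform(100, 500))  # conversation onset offset
            floor = np.nan
        else:
            floor = max(onset_prev + 1.0 - end_prev,
                        end_same[s] + config.max_gap_ms + 1.0 - end_prev)
            if sym:
                floor = max(floor, 183.0 - mean_next - d_k)
                if floor > mean_k - 1.0:  # safety net; unreachable by design
                    floor = mean_k - 1.0
            if config.fto_sd == 0:
                fto = mean_k
            elif config.fto_noise == "normal":
                a = ndtr((floor - mean_k) / config.fto_sd)
                fto = mean_k + config.fto_sd * float(
                    ndtri(rng.uniform(a, 1.0 - a)))
            else:
                # the skewed option's support is bounded below, so the
                # draw is kept as-is and T1 is extended with filler words
                # when the floor would bind; the group means stay exactly
                # configured at the cost of a mild coupling between T1
                # length and deep overlaps (why the symmetric normal is
                # the default for calibration studies)
                fto = _draw_fto(rng, mean_k, config.fto_sd, config.fto_noise)
                prev_all_ph = all(t["pos"] == "UH" for t in turn_tokens_prev)
                while fto < floor:
                    gap = float(rng.uniform(20, 160))
                    if prev_all_ph:
                        ph = _PLACEHOLDERS[int(
                            rng.integers(0, len(_PLACEHOLDERS)))]
                        orth, posx, syl, i, base = (ph, "UH", 1, -1,
                                                    ph_base[ph])
                    else:
                        i = int(rng.choice(len(words), p=wprob))
                        orth, posx, syl, base = (str(words[i]),
                                                 str(wpos[i]),
                                                 int(wsyl[i]), wexp[i])
                    dur = max(30.0, base * rates[1 - s]
                              * float(rng.lognormal(0.0, 0.25)))
                    start = end_prev + gap
                    turn_tokens_prev.append(
                        {"orth": orth, "pos": posx, "start": start,
                         "end": start + dur, "syl": syl,
                         "laughter": False, "idx": i,
                         "act": turn_tokens_prev[-1]["act"]})
                    end_prev = start + dur
                    floor = max(onset_prev + 1.0 - end_prev,
                                end_same[s] + config.max_gap_ms + 1.0
                                - end_prev)

        onset = end_prev + fto if k > 0 else fto
        this_tokens = [dict(t, start=t["start"] + onset,
                            end=t["end"] + onset) for t in toks_rel]

        # --- parse for the turn ---
        content = [t for t in this_tokens if t["idx"] >= 0]
        if content:
            nc = _act_clauses(plan["first_act"], len(content), scheme)
            parses[(conv_id, k)] = [_make_parse(
                [t["orth"] for t in content],
                [t["pos"] for t in content], nc)]
        else:
            parses[(conv_id, k)] = [TreeNode(
                "INTJ", [TreeNode("UH", [t["orth"]]) for t in this_tokens])]

        # --- flush the previous turn's tokens, record ground truth ---
        for td in turn_tokens_prev:
            tokens.append(WordToken(
                conversation_id=conv_id, speaker_id=spk_ids[(k - 1) % 2],
                orth=td["orth"], start_ms=td["start"], end_ms=td["end"],
                pos=td["pos"], lemma=td["orth"], dialog_act=td["act"],
                laughter=td["laughter"], n_syllables=td["syl"]))
        if k > 0:
            prefix_rel = (this_tokens[plan["n_prefix"]]["start"] - onset
                          if plan["n_prefix"] and len(this_tokens) >
                          plan["n_prefix"] else
                          (d_k if plan["all_ph"] else 0.0))
            gt_rows.append({
                "conversation_id": conv_id, "transfer_index": k - 1,
                "t1_turn_index": k - 1, "t2_turn_index": k,
                "seq_type": seq_k, "fto_drawn": fto,
                "t1_act": prev_last_act, "t2_act": plan["first_act"],
                "t1_laughter": prev_laughter, "t2_laughter": plan["laughter"],
                "t1_male": sexes[1 - s] == "male",
                "t2_male": sexes[s] == "male",
                "t1_rate_factor": float(rates[1 - s]),
                "n_placeholder_prefix": plan["n_prefix"],
                "placeholder_prefix_ms": float(prefix_rel),
                "t2_all_placeholder": plan["all_ph"],
                "t1_extended": prev_extended,
                "feasible_floor_ms": float(floor),
                "excluded_by_limit": abs(fto) > 2200.0,
            })
        if k > 0:
            end_same[(k - 1) % 2] = end_prev
        turn_tokens_prev = this_tokens
        prev_last_act = plan["turn_acts"][-1]
        prev_laughter = plan["laughter"]
        prev_extended = self_extended
        onset_prev = onset
        end_prev = this_tokens[-1]["end"]
        seq_k, mean_k = intended_mean(
            plan["turn_acts"][-1], plan_next["first_act"],
            plan["laughter"], plan_next["laughter"], t1_slot=s)
        plan = plan_next
        k += 1
    for td in turn_tokens_prev:  # final turn
        tokens.append(WordToken(
            conversation_id=conv_id, speaker_id=spk_ids[(k - 1) % 2],
            orth=td["orth"], start_ms=td["start"], end_ms=td["end"],
            pos=td["pos"], lemma=td["orth"], dialog_act=td["act"],
            laughter=td["laughter"], n_syllables=td["syl"]))
    return tokens, parses, gt_rows, speakers


def generate_corpus(config: GeneratorConfig,
                    seed: Optional[int] = None) -> SyntheticCorpus:
    """Generate ``config.n_conversations`` conversations plus resources."""
    seed = config.seed if seed is None else seed
    scheme = default_scheme()
    bundle = generate_lexicon(config, seed=seed)
    lexicon, unit_stats, _ = bundle
    tokens_by_conv: Dict[str, List[WordToken]] = {}
    parses: Dict[Tuple[str, int], List[TreeNode]] = {}
    speakers: Dict[str, SpeakerMeta] = {}
    gt_all: List[dict] = []
    for c in range(config.n_conversations):
        conv_id = f"sw{c:04d}"
        rng = np.random.default_rng([seed, c])
        toks, prs, gt, spk = generate_conversation(
            config, conv_id, rng, lexicon_bundle=bundle, scheme=scheme)
        tokens_by_conv[conv_id] = toks
        parses.update(prs)
        speakers.update(spk)
        gt_all.extend(gt)
    return SyntheticCorpus(
        tokens_by_conv=tokens_by_conv, parses=parses, lexicon=lexicon,
        unit_stats=unit_stats, speakers=speakers,
        ground_truth=pd.DataFrame(gt_all), config=config)
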