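# Methods

This note documents the models, conventions and numerical choices behind
`turntaking`, in the order data flows through the pipeline.

## Turn segmentation and FTO

A turn is a maximal run of one speaker's time-aligned words in which no
inter-word silence reaches `max_gap_ms` (default 180 ms; the comparison
is strict, so a gap of exactly 180 ms splits). Floor transfers are read
off the onset-sorted turn sequence: every consecutive pair with distinct
speakers yields one transfer, so a turn is T2 of one transfer and T1 of
the next. The FTO is `start(T2) − end(T1)`; values outside
±`fto_limit_ms` (default 2200 ms, boundary kept) are excluded as
lapses/long overlaps.

Fully contained T2s (ending at or before T1's end — typically overlapped
backchannels) count as transfers by default and carry a `contained`
flag; `include_contained=False` skips them, in which case the containing
turn remains T1 for the following transfer. Identical onsets are ordered
by speaker id.

Turn-preserving placeholders are identified lexically (case-insensitive
"uh"/"um"/"well" after punctuation stripping; the default, because the
lexical convention is the more reproducible of the two) or by the POS
tag UH. The stripped FTO is measured to the onset of T2's first
non-placeholder word; T2s consisting only of placeholders have no
stripped FTO and are excluded from stripped-response analyses.

## Sequence-organization coding

The shipped scheme (`data/act_scheme.csv`) maps each of the 43 NXT
dialog acts to its expected-next set, initiating/responding/
response-token flags and valence. A transfer is coded on T1's *final*
and T2's *first* act: T1's last action is what T2 responds to.
Adjacency-pair status requires the conjunction — T2's act expected after
T1's act AND T1 initiating AND T2 responding — so statement→statement
(a well-formed continuation between non-initiating acts) is not a pair.
Note the expected-next sets are kept exactly as the inventory defines
them and may contain labels outside the 43 (e.g. "accept"); these are
inert in the pair test.

Preference is gated on T1's coding act being in the question/commit set
{open-q, tag-q, wh-q, yn-q, yn-decl-q, commit}; within that set, a T2
containing any accepting act {affirm, yes, answer} is preferred, all
others dispreferred. "Backchannel" status considers any act of the turn
by default (`backchannel_any_act=False` restricts it to the coding act).
Laughter classification is four-way: both (invited), t1_only, t2_only
(volunteered), neither; a token is laughter if flagged or if its
orthography contains `[laughter` (the transcript convention).

## Processing measures

All lexical measures are means over the turn's words that have a lexicon
hit under the key (lemma, coarse POS); coverage is tracked and
complete-case filtering happens downstream. Lemmas default to a
rule-based de-inflection (plural -s/-es on NNS; -s/-ed/-ing on inflected
verb tags, with consonant-undoubling and CVC e-restoration heuristics —
deliberately light-weight, adequate for frequency pooling rather than
linguistic analysis). Penn tags collapse to their family (NNS→NN,
VBD→VB, PRP$→PRP, …).

* **Mean log frequency**: mean of ln(frequency per million + 1); raw
  counts selectable. Corpus-internal lexicons can be built with
  `build_frequency_lexicon`, which also computes contextual diversity
  (number of distinct conversations containing the (lemma, POS)).
* **Information uniformity**: mean absolute deviation of word surprisal
  from the turn mean ("mean deviation" read literally, not SD); 0 iff
  all surprisals are equal, and scale-equivariant (×c scales it by |c|).
  Token (not type) means are used.
* **Speech-rate delta**: (observed − expected)/expected where observed
  is the *summed token duration* (inter-word gaps excluded, since they
  would dominate short turns) and expected the summed corpus mean
  duration of the turn's units. Word-level by default; a per-syllable
  mode exists. Unseen units fall back to the table's global mean.
  Positive = slower than expected.
* **Tree height**: maximum number of nodes between the root and any tip
  (i.e. the deepest category path minus the root), so `(S)` has height 1
  and `(S (NP (PRP I)))` height 2; terminal word strings never count.
  **Clause count**: nodes labeled exactly `S` summed over the turn's
  parses.

## Feature matrix

One row per transfer: response `fto_ms` (raw or placeholder-stripped)
and 30 predictors — the nine measures above for T1 and T2, eight
sequence-organization variables (initiating/responding/backchannel for
both turns, T2 valence, preference), two laughter flags, two speaker
sexes. Only complete cases enter the model; a drop log records how many
rows each predictor eliminated. Categorical predictors are pandas
categoricals; for tree fitting they are ordinal-encoded by alphabetical
level (an approximation for the two three-level variables, acceptable
because binary splits on a 3-level code can still isolate every level
pair within two levels of a tree).

## Forest and permutation importance

The forest fits `n_trees` = 1000 regression trees; each tree sees a
bootstrap sample of the rows and a random `m_try` = 3 of the predictors.
The default base learner is a **significance-gated tree**: at each node
every available predictor is tested for association with the response
(Pearson correlation test on numeric codes), p-values are
Bonferroni-corrected across the node's predictors, and the node becomes
a leaf if nothing reaches α = 0.05; otherwise the most significant
predictor is split at its variance-minimizing cutpoint (at most 64
quantile candidates, both children ≥ `min_samples_leaf` = 20 rows).
This matters for the importance statistic below: a tree that never
splits on an uninformative predictor contributes an exactly-zero
permutation difference, so spurious predictors sit honestly near zero.
Plain CART (grown to the leaf floor) is available as `engine="cart"`,
but its overfitted noise splits inflate the *normalized* importance of
pure-noise columns — the normalization is scale-free, so consistency,
not magnitude, is what it rewards.

Importance of predictor *j*: over the trees whose subset contains *j*,
compute on each tree's out-of-bag rows the MSE with column *j* permuted
minus the baseline MSE (one fresh permutation per (tree, predictor),
seeded from the master seed via `permutation_stream`, so an independent
recomputation can replay them exactly); report mean/SD of these
differences (0 if the SD is 0). Trees not containing *j* are excluded —
their difference is structurally zero and would make the SD measure
tree-inclusion rather than signal. Ranks are tie-broken by predictor
name. Because the statistic is SD-normalized it measures *consistency*
of the error increase; the magnitude property ("a duplicated predictor
shares, and cannot exceed, the original's importance") holds for the
forest-wide mean difference with zeros included, which the test suite
checks in that form.

Diagnostics: a single significance-gated tree fit on all predictors
gives the predicted-vs-observed Pearson r (reported as 0 with a warning
when the tree makes no splits) and the gap/overlap sign accuracy (FTO =
0 counts as gap); an OLS fit on the same matrix gives the linear R².
Descriptives include a KDE mode: Gaussian kernels with the
0.9·min(SD, IQR/1.34)·n^(−1/5) rule-of-thumb bandwidth on a 512-point
grid extending 3 bandwidths past the data (the R `density()` default
behavior, cross-checked against Rscript in the tests). Post-hoc group
contrasts are Welch two-sample comparisons, reported raw (no
multiple-testing correction, matching standard practice for descriptive
post-hocs on a single pre-ranked model).

## Synthetic conversation generator

The generator emulates the statistical structure of a Switchboard-style
corpus; its defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `target_duration_ms` | 300 000 | ~5-minute conversations |
| `transfers_per_min` | 12 | floor-transfer rate |
| `fto_means_by_type` | 200.7 / 284.8 / 298 / 157 | mean FTO (ms) for init→resp, resp→init, init→init, resp→resp transfers |
| `fto_mean_other` | 187 | mean for transfers with unflagged acts (the corpus grand mean) |
| `fto_sd` | 448 | FTO noise SD (ms) |
| `laughter_both_mean` | −142 | group mean under invited laughter (replaces, not offsets, the type mean) |
| `male_effect_ms` | 70 | FTO increase per male speaker, applied mean-centered (±35) |
| `rate_slope_ms` | −262 | ms of FTO per unit of T1 rate delta; with rate SD 0.15 this reproduces a ≈100 ms fastest-vs-slowest-quartile contrast, faster T1 → longer FTO |
| `backchannel_overlap_prob` | 0.35 | validation target: N(157, 448) already implies P(FTO<0) ≈ 0.36 for resp→resp transfers, so no extra mechanism exists |

Dialog acts follow a Markov chain over the inventory: after an
initiating act, its expected-next set is up-weighted
(`adjacency_bias` = 0.6) and with probability `repair_prob` = 0.06 the
next turn is a repair initiator (itself initiating — the main source of
init→init transfers, as in real other-initiated repair); after a
responding act, response tokens are up-weighted
(`response_continuation_bias` = 0.35, assessment/receipt chains). Word
counts per turn are geometric with act-dependent means (backchannels
~1–2 words, statements long), globally calibrated against the chain's
stationary distribution so the realized transfer rate matches the
configured one. Parses are right-branching S-chains with act-dependent
clause counts; response tokens get clause-free INTJ fragments. A
configurable fraction of turns opens with 1–2 placeholders, and ~1% are
placeholder-only.

**Timing feasibility without bias.** Turn onsets must be strictly
ordered and a speaker's consecutive turns must stay more than the
gluing gap apart, or extraction could not recover the generated turns.
Each turn is therefore planned one step ahead: the minimum feasible span
of the current turn is computed from the intended means of both flanking
transfers, the turn is pre-extended with filler words where needed
(decided *before* any FTO is drawn, so extension never correlates with
an FTO residual; placeholder-only turns are extended with placeholders),
and the FTO is then drawn from a normal truncated *symmetrically* about
its intended mean. Symmetric truncation leaves every group mean exactly
at its configured value; the price is a reduced realized SD (typically
~380 ms rather than 448) and a bounded right tail after short turns.
Under the all-effects-zero null configuration no extension occurs at
all, which is what makes honest null calibration of the forest possible.
A right-skewed option (`fto_noise="lognormal"`, shift-scaled to the
configured mean and SD, σ = 0.6) exists for distributional realism; it
preserves means by extending T1 instead (its support is bounded below),
which mildly couples T1 length to deep overlaps — use the default
normal for calibration studies.

Ground truth is exported per transfer: sequence type, drawn FTO,
speaker sexes and rate factors, laughter flags, placeholder prefix
duration, pre-extension flag, feasibility floor, and whether the
transfer exceeds the ±2200 ms limit.

**What the generator does not emulate.** Semantically coherent words
(the lexicon is synthetic, Zipf-distributed with drawn concreteness/
surprisal values); prosody and acoustics; fully contained backchannels
deeper than the feasibility margin; more than two speakers; real
corpora's joint distribution of predictors beyond the injected effects
(e.g. the marginal T1-responding contrast here is structurally ≤ 30 ms
because only the four type means are fixed, whereas a real corpus showed
a ~50 ms contrast). Passing recovery tests therefore shows the pipeline
measures what the generator injected — not that real-corpus effect sizes
would be identical.

## Study sizes used in the test suite

End-to-end validation runs 350 conversations (~21,000 transfers,
matching the scale of the corpus study), 1000-tree forests with
m_try = 3, a 20-run seed battery for the signal-above-noise ranking
check, and a 60-conversation null battery. Predictors required to beat
appended pure-noise columns are selected a priori from the ground truth
(marginal Pearson |t| > 6 against the drawn FTO): under the default
conditions these are the speaker sexes, T1 rate delta and the laughter
flags; the initiating/responding flags carry real but marginally
undetectable signal at this size (see above) and are checked via their
group means instead. The null baseline band is |importance| <
5/√(n_trees·m_try/p), the 5σ envelope of a mean/SD ratio over the
~n_trees·m_try/p trees containing a predictor.

## Known limitations

* The conditional-tree association test is a Pearson correlation on
  ordinal-encoded values — categorical predictors with many levels or
  non-monotone effects would be under-served (all shipped categoricals
  are 2–3 levels).
* De-inflection is heuristic; irregular forms pass through unchanged.
* The TextGrid reader handles interval tiers only (no point tiers) and
  assumes well-formed files.
* `speech_rate_delta` at word level conflates speaker rate with word
  choice when the unit table is built from a different corpus.
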