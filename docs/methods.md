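# Methods

## Data model and assumptions

A *case* is one participant's recorded search session. Three streams describe
it: the think-aloud narrative (primary; one sentence per line = one
utterance, the smallest codable unit), the HCI transcript, and the screen
content (stimulus) stream. All three carry the same inline token layer:
qualitative codes `[[Label]]`, patch identifiers `[[patch_<case>_<ordinal>]]`
that persist until the next identifier, anchors `[[anchor:<id>]]` at patch
transitions, and optional explicit utterance identifiers `[[uid=<id>]]`.
Where the published source dialect leaves token syntax unspecified, this
package declares its own: anchors and uids get an explicit `anchor:`/`uid=`
prefix so the three token roles are syntactically unambiguous, and uids are
generated deterministically from (case, stream, line index) when absent.
Token-only lines update parser state but emit no utterance.

Alignment assumes anchors are unique within a stream and occur in the same
relative order in every stream; because anchors sit at patch transitions,
inter-anchor intervals coincide with patches (the parser cross-checks this
and warns on disagreement). Secondary-stream codes are attributed at
*interval* granularity — there is no finer cross-stream timing in the data
model — and the binary indicator is written on the first primary row of the
interval. This keeps every code column 0/1 and makes total code mass exact:
per-utterance (utterance, code) pairs for the primary stream plus distinct
(interval, code) pairs per secondary stream. Raw within-interval
multiplicity of secondary codes is deliberately not preserved; binary
columns cannot represent it.

## Co-occurrence networks

For each unit (case), the co-occurrence count of every unordered code pair
is accumulated within conversations (patches). Two stanza rules are
provided:

* `whole_conversation` (default — the conversation *is* the patch): a pair
  counts once per conversation if both codes appear anywhere in it;
* `moving_window(k)`: for utterance *t*, a pair counts once if one code is
  on line *t* and the other occurs in lines *t−k+1 … t*. `k` is in
  utterances; the default of 4 is an ordinary short-stanza choice and is
  fully configurable, since no single window is canonical.

Co-occurrence is binarized within a window (a pair never counts twice for
one window), matching the binary code columns. Each unit's vector is scaled
to unit Euclidean length, which removes narrative-length effects and bounds
edge weights in [0, 1]; all-zero vectors are flagged, excluded from the
projection fit, and placed at the origin.

Projection to 2-D is either SVD of the mean-centred matrix or a two-group
means rotation: the first axis is the unit vector along the difference of
the two group means, the second the leading SVD direction of the residual
after removing the first-axis component. Because the overall centring makes
the two group means collinear with their difference, both means have a
second coordinate of exactly zero — the second axis only separates within-
group variation. Sign indeterminacy is resolved by forcing the largest-
magnitude loading on each dimension positive, which makes the projection
deterministic. Node positions solve the standard co-registration least
squares: minimize the squared distance between each unit's score and the
edge-weight-normalized centroid of its network's node positions
(`lstsq`, tolerance machine precision; perturbation tests confirm a local
minimum). Group means carry t-distribution confidence intervals per
dimension. Trajectory models re-accumulate each (unit, patch) alone,
normalize, and project into the fitted space, ordered by patch ordinal, so
each point is interpretable by its x-value, y-value and position in the
sequence.

## State transitions

A session is a walk over patch content types (`engine`, `SERP`, `page`,
`file` by default; the scheme is pluggable to support sensitivity analyses
over alternative codings). Adjacent pairs are tallied into an asymmetric
count matrix with self-loops on the diagonal; transitions are never counted
across units. Probabilities divide each row by its outgoing total; rows
without outgoing transitions (terminal states) stay zero and are flagged
absorbing rather than renormalized. Subsample models pool counts before
normalizing by default; averaging per-unit probability matrices is available
(`pooling="mean"`), since neither convention is canonical — pooling weights
units by activity, averaging weights them equally. Node statistics report
occupancy (total participant-states), self-reference proportion
(self-loops / occupancy, 0 for unvisited states) and summed dwell time when
per-patch durations exist. Exports omit state pairs with no transitions in
either direction entirely (no edge, rather than a zero edge).

## Information scent

Codes are collapsed per patch per stream into presence indicators. The
derived variable per (patch, code) cell is +1 when the stimulus occurred and
was engaged with — engagement means code presence in the think-aloud *or*
the HCI stream — −1 when it occurred unengaged, and 0 when absent. A noted
absence (the participant remarking that a feature is missing) also scores 0;
it is qualitative context, not scent. Misperceptions (engagement without a
stimulus) are out of scope and score 0.

Information scent is the grand sum of the derived matrix. The normalizing
maximum defaults to patches × codes (every cell can contribute at most +1),
giving a score in [−1, 1]; an alternative mode uses the number of
stimulus-present cells as the maximum, which lets richer patches contribute
more. The trajectory is the per-patch row sum and its cumulative series; the
full per-cell grid is retained for heat-map-style inspection.

Patch-feature frequencies binarize each code per patch, sum over a case's
patches and divide by the number of patches visited (so per-case values lie
in [0, 1]); subsample profiles sum the per-case values over members.

Cohen's κ = (p_o − p_e)/(1 − p_e) is implemented directly from the observed
and chance agreement; when chance agreement is 1 (both raters constant on
one label) the statistic is undefined and perfect agreement returns a
flagged 1.0. An intra-rater wrapper evaluates κ on the first half and the
full corpus to track coder drift.

## Synthetic sessions

The generator emulates the targeted study design: two subsamples (expert,
novice) of 10 cases each foraging through patches in a 10-minute task.
Ground-truth parameters, all configurable:

| parameter | default | rationale |
|---|---|---|
| patch count / case | uniform 4–12 | plausible URL changes in a 10-minute search |
| patch-type chain | engine-seeded, row-stochastic | engines lead to SERPs, SERPs mostly to pages |
| stimulus emission | 0.15–0.7 per code by patch type | pages/files are feature-rich, engines sparse |
| engagement prob. | expert 0.75, novice 0.45 | the configured group effect scent should recover |
| utterances / patch | uniform 2–6 | sentence-level narration density |
| dwell time | uniform 5–90 s | exercises dwell statistics |

Engagement, when drawn, surfaces in the think-aloud with probability 0.7
and in the HCI stream with probability 0.5 (forced into the think-aloud if
neither fires, so engagement is never silent). All randomness flows from a
single seed; output is byte-identical across reruns.

What the generator does *not* emulate: natural language (think-aloud text is
template filler — only token structure feeds the models), real web content,
coder disagreement or coding error, misperceptions, within-patch timing, and
revisits driven by memory rather than the Markov chain. Passing tests
therefore demonstrate correctness of the computational pipeline on
structurally faithful data, not validity of any substantive claim about real
foragers.

## Numerical choices and degenerate inputs

* Vector normalization: zero vectors returned as zero and flagged, never
  divided.
* SVD sign convention as above; ties in the largest loading resolved by the
  first index (`argmax`).
* Projection requires ≥ 2 nonzero units; means rotation requires exactly two
  groups with distinct means.
* Confidence intervals require n ≥ 2; absorbing transition rows are kept as
  zeros; self-reference proportion defined as 0 at zero occupancy.
* Probability row sums are validated to 1 ± 1e−9 in tests; counts are exact
  integers throughout.
* Test-suite problem sizes: corpora of 2–6 cases for pipeline tests and
  10,000-transition chains for parameter recovery, which keeps the whole
  suite in a few seconds while the recovery tolerance (max abs error
  < 0.05) is comfortably met.

## Known limitations

* Secondary-stream code multiplicity within an interval is collapsed (see
  above).
* Only pairwise co-occurrence is modelled; triads and higher-order
  co-occurrence are not representable in this network family.
* Transition models operate on content-type states, not individual websites;
  results depend on the chosen state coding scheme (hence the pluggable
  scheme).
* The normalized scent of sessions with different patch counts is comparable
  only under the default all-cells maximum; the stimulus-present mode trades
  comparability for richness sensitivity.
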