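# Methods

## The tripartite prescription network

One prescription record is a clinical encounter: a set of symptom tokens, a
set of (zero, one or two) syndrome tokens, a non-empty set of herb tokens,
and a binary outcome — `good` if the patient improved by the next
encounter. Token identity is exact string match after whitespace trimming;
no fuzzy name normalization is attempted, so the same herb spelled two ways
is two nodes. This keeps network construction deterministic and leaves
vocabulary curation to the data producer.

The network has three disjoint node sets (P symptoms, D syndromes, H
herbs). A cross-type pair gains one count per record containing both
tokens, regardless of how many times either token might be listed — counts
are record-level presence, matching the "observation number of
co-occurrence" reading of edge weight. Cross-type counts use all records;
the per-pair good/bad outcome tallies are kept separately so the relevance
filter can consume them. Homogeneous projections (P–P, D–D, H–H) count
co-membership in good-outcome records only: same-type co-prescription is
evidence of compatibility only when the treatment worked. Entity
frequencies F(x) count the records containing x, which bounds every pair
count by both members' frequencies.

### Virtual objects

Corpora that lack one entity type entirely (insomnia-style records without
syndromes, tic-disorder-style records without symptoms) are repaired
against a reference network that has all three types. For each observed
cross pair of the record — (p, h) when syndromes are missing — every
reference syndrome d lying on a p–d–h path is adopted. If at least one
pair matches nothing (or nothing matches at all), the record receives one
fresh virtual syndrome (`VIRT_0001`, numbered in record order), which links
to all its endpoints when the network is rebuilt. One virtual token per
record, not per pair, avoids a combinatorial explosion of singleton
syndromes while still satisfying the non-emptiness invariant. The choice
of reference corpus (same disease or another) is deliberately the
caller's: the operation takes an explicit reference network.

## Weighting schemes

Each block can be re-scored element-wise: frequency (raw count), Jaccard
(overlap of record sets), asymmetric measure (conditional rate given the
row token), TF–IDF (count damped by its unspecificity for the row token,
natural log). Conventions worth making explicit:

* AM and TF–IDF condition on the ROW entity of the block, so a weighted
  block reads "how strongly does this row token select that column token".
  The alternative — a corpus-level N in the IDF term — would change TF–IDF
  from a per-entity specificity weight into a global one; the per-entity
  form is used here.
* Every scheme maps a zero count to exactly 0 and a zero denominator to 0
  rather than NaN, so downstream cosines are always defined.
* TF–IDF is unimodal in the pair count with its maximum at F(x)/e and is
  exactly 0 at F(x, y) = F(x). A consequence users should know: tightly
  coupled pairs — a token that co-occurs with its partner in nearly every
  record it appears in — are weighted toward zero and can rank *below*
  weak spurious co-occurrences. On corpora with few syndromes, where a
  symptom is tightly coupled to its one or two syndromes, this inverts the
  symptom→syndrome profile and visibly degrades the mediated path under
  TF–IDF (the F/JC/AM schemes do not have this failure mode; the
  recovery experiment below quantifies it).

## Composite similarities and prediction

Symptom similarity (direct path) mixes the cosine of symptom rows in the
weighted P×H block with the cosine in the good-outcome P×P block,
λ₀·cos + λ₁·cos with λ₀ + λ₁ = 1. Syndrome similarity (mediated path)
mixes two inner blends: symptom-profile cosine (COLUMNS of P×D — a column
is a syndrome's symptom profile; the formula is written over syndrome
pairs and the rectangular blocks leave the orientation open, so this is
the package's resolution) with D×D, and herb-profile cosine (rows of D×H)
with D×D. All coefficients are validated to lie on their simplexes within
1e-9. Zero rows cosine to 0, so unconnected entities are dissimilar rather
than undefined. Defaults are the values tuned on an infertility validation
split: λ₀ = 0.8, α = 0.7, α₀ = β₀ = 0.8, θ = 0.5, K = 30, N = 30.

Rating is item-neighbourhood collaborative filtering. Direct path:
the K most similar symptoms (self excluded, ties broken by vocabulary
order) vote for their herbs, weighted by similarity. Mediated path: every
syndrome the symptom co-occurs with contributes its herb profile, smoothed
over its own K nearest syndromes — with the anchor syndrome participating
at similarity exactly 1, so direct p–d–h evidence is never discarded. Sums
are not normalized by the neighbour similarity mass: ratings are ordinal
scores, and only their ranking matters. Normalizing would not change the
neighbourhood composition but would re-scale ratings per entity; the
unnormalized form keeps the rating interpretable as accumulated weighted
evidence.

The pipeline per symptom is strictly: score all candidate herbs → sort
descending (ties by herb vocabulary order) → drop pairs with relevance 0 →
truncate to N. Filtering before truncation means the Top-N list still
contains N relevant patterns when enough survive.

### The relevance filter in held-out evaluation

R(p, h | θ) = 1 iff the pair co-occurs in at least one record AND its
good-outcome fraction is ≥ θ. Taken literally inside a held-out evaluation
this is contradictory: candidates are exactly the pairs absent from the
training half, so every candidate has zero training co-occurrence and the
filter would reject all predictions unconditionally. The package therefore
lets `tri_tspa` take a separate relevance network, and `evaluate` computes
outcome tallies on the full record set — treating the filter as a
dataset-level outcome-cleaning step, which is how a filter "of bad
outcome patterns" is usable at all alongside link prediction. This leaks
the *outcome* (not the ranking) of test records into the filter and is
flagged here deliberately; prediction on a single corpus (`tritspa
predict`) applies the strict filter with no leak.

## Matching function

The largest subset of a symptom's Top-N herbs that was prescribed together
in a single good-outcome record containing that symptom, ties to the
earliest record. The single-record ("longest chain") reading — rather than
a union over several records — guarantees every returned combination is
co-attested as one real prescription. Ratings are carried over unchanged;
the reduction never re-scores.

## Evaluation protocol

Twofold cross-validation: a seeded 50/50 record split; the network is
built on the training half; the recovery targets T_p are the symptom–herb
pairs observed in the test half but not in training, restricted to tokens
the training vocabulary knows (pairs with unseen tokens cannot be ranked
by any method); training pairs are excluded from the candidate set.
Precision@N = hits/N and Recall@N = hits/|T_p| are macro-averaged over
symptoms with at least one held-out pair — the macro form weights rare and
common symptoms equally, and per-symptom hit counts stay integers.
`chance_precision` provides the analytic baseline: for a uniformly random
ranking of symptom p's candidates the expected precision at any N is
|T_p|/|C_p|.

The grid search collapses the nine mixture parameters to six free
dimensions (λ₀, α, α₀, β₀, θ, K) via the simplex constraints and evaluates
each point on a validation split carved from the training half; a
full-simplex mode accepts raw nine-parameter grids and skips infeasible
corners. Argmax by Precision@N, first grid point on ties.

## Synthetic corpus generator

The generator emulates the published structure of private prescription
corpora; its defaults are the package's study conditions.

| parameter | default | rationale |
|---|---|---|
| q, m, n | 50 symptoms, 10 syndromes, 80 herbs | desk-scale corpus |
| records | 3000 | mid-sized specialist clinic |
| pools per syndrome | 10 symptoms, 18 herbs | matches the reported sharing rates: a symptom associates with ~19% of syndromes, a herb with ~23% |
| per record | 1–2 syndromes; 1+Poisson draws, means 1.5 symptoms / 4.5 herbs | prescription sizes scaled by vocabulary ratio (≈14 herbs of 251 → ≈4.5 of 80) |
| zipf_exponent | 1.0 | classic Zipf prevalence |
| noise_rate | 0.2 | off-pool contamination |
| mismatch_bad_prob | 0.8 | most mismatched treatments fail |

Mechanics: syndrome pools are drawn *uniformly* from the vocabularies —
pools are characteristic token sets, not popularity samples — and
popularity cascades from Zipf syndrome prevalence plus positionally
Zipf-decaying within-pool weights. (Popularity-sampled pools were
rejected: they make "planted" coincide with "popular", so any method, and
even a shuffled-syndrome control, reduces to the same popularity ranking.)
Symptom noise is per draw: each symptom escapes to a uniform vocabulary
draw with probability `noise_rate`. Herb noise is per record: with
probability `noise_rate` the entire herb set is drawn uniformly — a
mismatched prescription. A record whose herbs overlap its syndromes' pools
by less than half is labelled bad with probability `mismatch_bad_prob`;
this ties the outcome labels to a real mechanism the relevance filter can
exploit. Corpora are byte-identical given the seed.

Generated corpora reproduce: heavy-tailed entity rank–frequency tables
(log–log R² ≈ 0.85–0.9 at 2000+ records), power-law link-frequency
histograms (R² ≈ 0.9), one-to-many fanouts, good/bad outcome labels with a
~11% bad rate, and variants lacking one entity type. `planted_pairs`
exposes the ground truth — all symptom–herb pairs sharing a syndrome pool —
as the recovery target.

What the generator does NOT emulate, hence what passing tests do not show
about real data: herb–herb pharmacological synergy or antagonism (herbs
within a pool are exchangeable), longitudinal structure across a patient's
encounters, co-morbid syndrome correlations (syndromes are drawn
independently given prevalence), and free-text symptom variability
(records arrive tokenized by construction). Absolute metric values on
synthetic corpora say nothing about clinical accuracy; only relative and
structural claims transfer.

### Scale effects the recovery experiment exposes

At the default desk-scale conditions, 3000 records on a 50×80
symptom–herb grid observe most of the pair space directly. Two
consequences, both computed by `scripts/acceptance.py` rather than
asserted here: (i) the ratio of any method's Precision@30 to the analytic
chance level is bounded by n/30 ≈ 2.7, because hits ≤ min(|T_p|, 30) while
chance is |T_p| over a candidate set capped by the 80-herb vocabulary;
(ii) the direct and mediated paths perform near-identically — when direct
co-occurrence is densely observed it carries at least as much information
as the rank-m factorization through 10 syndromes, and under TF–IDF the
tight symptom–syndrome coupling additionally inverts the mediated path's
input (see Weighting schemes). The mediated path's distinctive value shows
up instead in the mediation test: on a flat-prevalence corpus, shuffling
syndrome assignments across records collapses mediated-path recovery to
the popularity baseline while the unshuffled corpus stays well above it.

## Numerical choices

* Natural log in TF–IDF; any fixed base only rescales ratings.
* Cosines are clipped to [0, 1] against floating-point overshoot; inputs
  are non-negative so true negatives cannot occur.
* All ties (neighbour selection, ranking, matching) break by vocabulary or
  record order, making every pipeline output deterministic for a fixed
  input and seed; vocabularies are sorted, so networks are
  order-independent.
* The power-law exponent is fitted by least squares on the log–log
  frequency-of-frequencies histogram; γ is minus the slope. A discrete
  maximum-likelihood (zeta) estimator is provided as an alternative. For
  rank–frequency plots (entities ordered by descending frequency) use
  `rank_frequency_fit`, which matches how such corpora are usually
  displayed.
* Degenerate inputs: empty test sets yield NaN metrics with a zero
  symptom count; fewer than 3 distinct count values refuse an exponent
  fit; unknown tokens in relevance lookups count as never-observed.

## Known limitations

* The KNN rating form is a reconstruction of a procedure whose printed
  description is informal ("discover K nearest entities … predict
  rating"); it is isolated behind `predict_rating`/`Predictor` so an
  alternative rating rule can be swapped in one place.
* K = 30 was tuned on a corpus with 106 syndromes; with 10 syndromes it
  includes every neighbour, and the neighbour mass dilutes the anchor
  signal roughly (1 + Σ sim) : 1. Scale K with the vocabulary when working
  at other sizes.
* The evaluation's relevance handling necessarily leaks test outcomes
  (section above); comparisons between configurations remain fair because
  every configuration sees the same filter.
* Grid search cost is the product of grid sizes times one evaluation each;
  the full 9-parameter grid at 0.1 steps is intractable by design and the
  collapsed 6-dimensional grid is the supported path.
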