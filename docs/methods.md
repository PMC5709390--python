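# Methods

## Model and assumptions

The method scores the potential of an endogenous hormone to interfere with a
drug's efficacy for a disease, using only network topology. It rests on three
assumptions: (1) hormones whose receptors sit closer (in shortest-path arcs)
to the drug's mechanism-of-action paths interfere more; (2) interference
grows with the number of receptors involved; (3) it grows with the number of
mechanism molecules touched. The network is a directed multigraph of genes
and compounds: protein–protein interactions, binding/association and
dissociation events are symmetric and materialized as reciprocal arcs, while
the six signaling/regulatory relation types (activation, inhibition,
expression, repression, phosphorylation, dephosphorylation) keep their stated
direction. Hormones, drugs and diseases are *not* network nodes; they enter
vicariously through receptors, targets and disease genes.

All distances count arcs (a path of k molecules has length k − 1), computed
by breadth-first search on the directed view. Unreachability is an explicit
infinite sentinel that compares greater than every finite length and turns
into a score of exactly 0.

**Drug effect paths (DEPs).** Per target, independently: the minimal BFS
distance to any disease gene defines that target's DEP length, and *every*
disease gene at that distance contributes all of its shortest paths (the
definition speaks of "the nearest disease gene" in the singular; keeping all
ties is deterministic and order-independent, so that is what we do). A target
that is itself a disease gene yields one zero-length, single-node DEP. The
molecule set M(d) is the union of every node on every DEP — upstream targets,
intermediates, and downstream disease genes alike, since crosstalk may land
anywhere on the mechanism. M(d) is assembled from the BFS predecessor DAG,
not from the listed paths, so the enumeration cap (below) can never change a
score.

**Hormone effect paths (HEPs).** One BFS per receptor, early-stopped once the
minimum distance to M(d) is final. The global minimum over all (receptor,
molecule) pairs is the HEP length; the start set S and end set E contain
exactly the receptors and molecules participating in a minimum-length pair —
not every receptor with some finite route — because HEPs are defined as the
*very shortest* paths only.

**Score.** i(h, d) = α^(−L) · n(S) · n(E) with L the HEP length. α defaults
to 8 and is accepted over (1, ∞) (practically swept over [2, 10]; ranking
performance saturates around 8 because larger bases only widen the gap
between consecutive integer lengths). For fixed n(S)·n(E), the relative order
of two pairs is independent of α; α matters only where length trades off
against endpoint counts.

## Path enumeration

Shortest-path counts are exact, computed by dynamic programming over the BFS
predecessor DAG — never by enumeration, since counts grow combinatorially
(a stack of six diamonds already has 64 shortest paths). The listing cap
(default 100 per source–sink pair) affects reporting only; listed paths are
emitted in lexicographic node-id order so reports are byte-reproducible.

## Evaluation protocol

Gold hormone→drug pairs come from a directional drug–drug-interaction table
whose rows are pre-classified as enhances / disturbs / adverse / unknown
(the free-text classification itself is curation, supplied as input);
unknown rows are dropped, direction is preserved, and a pair is kept only if
the recipient drug treats the disease under study. Unlabeled
(presumed-negative) pairs are sampled uniformly without replacement from
hormone × disease-drug pairs outside that disease's gold set — gold pairs of
*other* diseases are not excluded — in five independent replicates (overlap
between replicates allowed) at 1, 3, 5, 7 and 10 times the gold size;
replicate i uses seed + i. If the universe is smaller than requested, the
whole universe is taken and the dataset flagged truncated.

AUROC is the midrank-corrected Mann–Whitney statistic (equal to the
trapezoidal area under the ROC curve; the suite asserts agreement to 1e-12
and cross-checks scikit-learn). AUPR is the non-interpolated step area.
Drugs with no usable DEP set stay in the output at score 0 so dataset sizes
are stable. The HEP-length comparison between gold and unlabeled pairs uses
a univariate Welch two-sample t-test on per-pair finite lengths — the
compared quantity is a scalar mean, so no multivariate machinery is needed —
with unreachable lengths excluded from means but counted as "not ≤ 1" in the
percentage summaries. A repeated stratified-fold generator (10 folds × 30
repeats, identical positive:unlabeled ratio per fold) is provided as a
cross-validation harness; no training happens, since the score has no fitted
parameters beyond α.

## Synthetic worlds

The generator emulates the shape of the real inputs — a mixed directed/
bidirectional molecular network plus receptor, target, disease-gene,
disease-drug and classified-DDI tables, written in the package's own TSV
dialects so every test exercises the real I/O path — without emulating their
content. Defaults (chosen once as a realistic desk-scale study condition):
2 diseases, 8 drugs assigned round-robin, 12 hormones with 1–3 receptors,
1–3 targets per drug, DEP chain lengths drawn from 0–3, 3 gold pairs per
disease wired receptor→target at HEP length 1, and non-gold pairs either
wired at length ≥ 4 (probability 0.5) or left disconnected from that drug's
machinery. Twelve hormones × four drugs per disease give a 45-pair non-gold
universe per disease, so even the 10× multiplier (30 pairs) never truncates.

Chains always use fresh intermediate nodes, each target's nearest disease
gene is private to it, and the random filler subgraph (40 genes, 6
compounds, arc density 0.05, half the arcs reciprocal PPIs) never feeds into
the planted machinery — receptors may point into it, not out of it — so the
planted/background length contract holds structurally; a post-hoc verifier
(`verify_length_contract`) re-derives every HEP length with the path-finding
machinery and is run in the tests anyway. `label_noise` rewires exactly
round(noise · |gold|) gold pairs background-style (an exact-fraction flip
rather than a Bernoulli draw per pair, so the realized noise level is the
stated one). Every node is guaranteed at least one incident arc because the
edge-table dialect cannot represent isolated nodes; this is what makes
write→read→rescore round trips bit-identical.

What passing these benchmarks does *not* show: real interactomes have hubs,
heavy-tailed degree distributions, correlated annotation errors and
literature bias, none of which the generator reproduces. Synthetic results
demonstrate correctness of the machinery and behavior under controlled
signal/noise, not real-data predictive performance.

## Numerical and design choices

- Distances are exact integers; the only floating-point arithmetic is the
  final score, evaluated in closed form.
- Ranking ties are broken lexicographically by (hormone, drug) for
  reproducible reports; AUROC handles ties via midranks instead.
- Candidate selection keeps unlabeled pairs with rank ≤ 10 and score > 1.0,
  both configurable.
- The disease→drug (treatment) map is accepted as a pre-filtered table; the
  upstream relation type that defines "treating" is left to the data
  curator, and the loader records what it dropped in a machine-readable
  audit.
- Receptor ablation (`ablation_rescore`) rebuilds nothing implicitly: it
  copies the network, removes the nodes, and rescores, so the caller can
  diff scores pair by pair.

## Known limitations

- Unweighted arcs: all interactions count equally; confidence weights and
  edge signs (activation vs inhibition) do not modulate the score.
- The score is purely topological — no expression data, tissue context, or
  hormone concentration enters.
- The edge-table writer collapses a reciprocal arc pair back to one
  `directed=0` row only when both directions carry identical, purely
  bidirectional label sets; provenance strings are merged per arc.
- Evaluation treats unlabeled pairs as negatives, which understates true
  performance if unknown true interactions are sampled.
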