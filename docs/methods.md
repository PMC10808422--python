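# Methods

This note documents the models, parameters and design choices behind
`facilink`: what the consolidation pipeline assumes, what the synthetic
registry generator does and does not emulate, and where the numerically
consequential decisions lie.

## The consolidation model

The package treats facility-list consolidation as blocked entity
resolution. Its core assumptions:

* **Region identity is reliable.** Candidate matches are generated only
  within a first-level administrative region (blocking). A facility listed
  under two different regions will never be merged automatically — only a
  manual merge decision can join records across blocks. Records whose
  region does not canonicalize against the 14-region list are kept
  verbatim in their own block and flagged, never guessed.
* **Names identify facilities once type decoration is removed.** Sources
  render the same facility as "PS Nemataba", "Nemataba Poste de Santé" or
  "NEMATABA"; after normalization all three reduce to `nemataba`. The
  normalization order is fixed — accent stripping and special-character
  removal first (destructive steps early), then lowercasing, type-token
  removal, acronym expansion, terminal roman-numeral conversion, and
  whitespace collapse — and the transform is idempotent, which the tests
  assert. Type tokens are removed at any word boundary, not only as
  prefixes, and the removal never touches token-internal substrings
  ("ps" in "Passy" survives). Accent handling transliterates to ASCII
  rather than deleting, since deleting accented letters would corrupt
  French orthography ("Santé" → "Sant").
* **Edit similarity is enough.** Matching uses the plain Jaro–Winkler form
  `1 − [J + ℓ·p·(1 − J)]` with the standard constants `p = 0.1`,
  `ℓmax = 4`, and acceptance at distance ≤ 0.2 (similarity ≥ 0.8). The
  conventional "only boost when J > 0.7" variant is deliberately not
  applied; at the 0.2 threshold the two variants rarely disagree, and the
  plain form matches the formula stated above exactly. No phonetic
  encodings are used.
* **Transitive closure mirrors the review workflow.** Accepted pairs are
  clustered single-linkage via union-find: a chain of pairwise matches is
  one facility until a reviewer splits it. A stricter complete-linkage
  mode (scipy agglomerative clustering cut at the threshold) is available
  behind `MatchingConfig(complete_linkage=True)` for users who prefer
  over-splitting to over-merging. Group identifiers are assigned
  deterministically — groups ordered by (region, lexicographically
  smallest match name, first source order/row), ids `region-NNNN` — so
  re-runs and input permutations give identical output.

### Type resolution

When member records disagree on facility type, the common real-world cause
is an upgrade (health hut → health post, health post → health center), so
conflicts on the upgrade ladder are resolved to the type reported by the
most recently dated source, with a note recording the direction. Undated
sources rank oldest. Conflicts involving off-ladder types (autre), or with
no dated member, fall back to majority vote with ties going to the higher
tier; these are flagged as unresolved. Re-running the resolution pass on
its own output is a no-op.

### Geospatial verification

Distances use the Haversine formula on a sphere of mean radius 6371 km —
adequate at the sub-percent level against the WGS84 ellipsoid for the
kilometre scales that matter here. Two thresholds apply, both strict
inequalities: member coordinates more than 1 km apart flag the group for
review; among groups with at least two *distinct* coordinate sets (5-decimal
rounding, ≈1 m, defines distinctness), the share more than 2 km apart is
reported as the discordance rate. The 1 km rule uses the maximum over all
member pairs, not just the preferred-vs-rest comparison.

### GPS assignment

One coordinate pair per group, chosen by an ordered source-preference
hierarchy (configuration, not code). The shipped default encodes the
government-first ordering used for Senegal: COUS, then the non-2017 SPA
frames in the order 2016, 2015, 2014 (the within-tier order is treated as a
preference and is configurable), then SPA 2017, ESRI, HDX, and the Maina
et al. spatial database. Sources absent from the hierarchy rank last in
run-configuration order. If one source contributes two distinct coordinate
pairs to a group, the first by row order is used and the group is flagged.
No averaging of discordant coordinates is performed — one source wins.

## Output schema

The consolidated list carries exactly: region, match_id, match_name,
group_fac_type, group_latitude, group_longitude, group_gps_source, n_gps,
n_source, source_list, data_flagged, data_notes. Type labels are written in
accent-free French ("hopital", "centre de sante", "poste de sante", "case
de sante", "autre"). `data_flagged` is 1 exactly when `data_notes` is
non-empty. Rows typed autre/unknown are carried in the file but excluded
from headline counts and coverage percentages. The full per-record list
(original names, types, ownership, admin units, per-source coordinates) is
linkable through match_id, and cross-group same-name merges are never
automatic — they surface in the review report for a human decision, since
that judgement requires local knowledge.

## The synthetic registry generator

The generator emulates the error structure of real multi-source facility
lists: overlapping partial coverage (independent per-source inclusion),
type decoration and orthographic noise on names (type prefixes/suffixes,
accent stripping, "Saint"↔"St." contraction, roman-numeral toggling,
single-character typos/transpositions), stale types from pre-upgrade
sources, per-source GPS missingness, metre-scale isotropic coordinate
jitter (applied in metres, converted to degrees at the local latitude), and
within-source duplicate rows. Every emitted record maps to its true
facility, and a fixed seed fully determines the output.

Reference conditions (the defaults): 500 facilities across the 14 regions
with a type mix of 2% hospitals, 5% health centers, 50% health posts, 43%
health huts (proportioned like the national facility mix); 5 sources dated
2014–2022 at two-year steps; 70% inclusion and 80% GPS reporting per
source; 100 m jitter; typo probability 0.05; 10% upgrade probability among
upgrade-eligible facilities with the upgrade year drawn strictly inside the
source-year span (so both the old and new type are observable); 2%
within-source duplication. These sizes keep a full pipeline run within a
few seconds while leaving every subsystem exercised.

Two generator choices are deliberate idealizations:

* **Name separability.** Canonical names are rejection-sampled so that,
  within a region, no two true facilities sit within Jaro–Winkler distance
  0.22 of each other. This makes ground truth identifiable in principle —
  the noise-off identity (precision = recall = 1 with all noise disabled)
  is then a meaningful correctness check rather than a property of the name
  draw. Real registries violate this ("PS Mlomp" twice in Ziguinchor), which
  is exactly what the same-name flagging and review machinery is for;
  passing synthetic tests therefore does not certify performance on
  pathologically self-similar real name sets.
* **Jitter law.** Each observation's coordinates are displaced by
  independent per-axis Gaussian noise of standard deviation σ. Two
  observations of one facility then sit at a Rayleigh(σ√2) distance with
  `P(d > r) = exp(−r²/4σ²)`; at σ = 500 m, 36.8% of pairs exceed 1 km. The
  Monte-Carlo test asserts this closed form. At the default σ = 100 m
  essentially no pair exceeds the 2 km discordance threshold, so the
  reference run's discordance rate is ~0 by design, not by coincidence.

Other simplifications: all synthetic sources are dated (real lists often
are not — undated sources are supported by the resolver and rank oldest);
ownership is not simulated; private-sector under-coverage, facility
openings/closures and name changes over time are not modelled.

## Numerical choices

* Jaro transpositions are counted as half the number of out-of-order
  matched characters, without flooring, matching the formula used
  throughout.
* Threshold comparisons: a pair matches when distance ≤ threshold; geo
  flags fire when distance > threshold. Ties therefore match and do not
  flag, respectively.
* Coordinates are rounded half-even to 5 decimals on output; coverage
  percentages are rounded half-up to 1 decimal.
* Malformed or out-of-range coordinates in inputs become missing values
  with a warning; empty names reject the row with a log entry; names that
  normalize to the empty string are kept and flagged.
* Evaluation counts pairs through the group×entity contingency table
  (linear in records); the tests check it against an explicit all-pairs
  double loop. Precision is defined as 1 when no pair is predicted, recall
  as 1 when no true pair exists.

## Run configuration

A YAML file drives real-data runs: one entry per source (source_id, path,
year, column map, optional delimiter), plus optional `matching`, `geo`,
`hierarchy` and `lexicon` blocks. The normalization lexicon (type tokens,
acronym expansions, roman-numeral limit) is data, not code, and can be
extended per run; the same is true of the GPS hierarchy. The `facilink`
CLI exposes `simulate`, `run` (with `--review` for split/merge decision
files), `evaluate` and `report` subcommands over the same library surface.

## Known limitations

* Cross-region duplicates are invisible to the automatic matcher by
  design; they require review decisions.
* The packaged reference-count table for comparisons carries only the
  nationally published totals transcribed from the SPA facility-frame and
  Health Map reports; regional reference breakdowns are not shipped.
* Single-linkage clustering can chain distinct facilities through an
  intermediate noisy record; the near-threshold review report and the
  complete-linkage mode are the mitigations.
* Distances are spherical, not ellipsoidal; errors are well under the 0.5%
  level the conflict thresholds care about.
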