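# Methods

## The valuation model

A biomedical record is the triplet *(type, time, quality)*: a categorical
type key, the patient's age at sampling in years, and a nonnegative scalar
quality. A dataset of N *(user, record)* pairs is priced as

    Cost(Dataset) = Σ_users Cost(user) + Σ_types GroupCost(type)

**Per-user terms.** For each user, every combination of k of their records
(k = 1 .. `max_combination_order`, default 4) contributes

    f_k = Ψ_k(type₁…type_k) · v_k(quality₁…quality_k) · τ(time₁…time_k)

* Ψ₁ is the record type's base value (LifePounds) times the user's
  `base_value_modifier` (default 1). For k ≥ 2, Ψ_k is looked up in the
  synergy table by type multiset and is **0 when undeclared** — the model
  is sparse by construction, so Cost(user) reduces to the sum of single
  terms unless interactions are declared, and the subset enumeration only
  expands combinations matching a declared key (polynomial in the record
  count per key). A per-user cap of 64 records (configurable) guards
  against accidental blow-ups and raises an explicit error rather than
  truncating.
* v_k is the quality aggregator, default the reciprocal sum
  (Σ_m 1/q_m)⁻¹: monotone nondecreasing in every argument, equal to q for
  a single record, and 0 as soon as any member quality is 0. A zero-quality
  record is a valid but worthless record; this propagates to every term it
  touches, so adding one never changes any price (tested over 1000 random
  datasets at 1e-12).
* τ is the **time value**, in [0, 1]. Each type carries a half-life T
  (years) and a decay kernel; the default kernel w(u) = 2^(−|u|) with
  u = (t − time − t₀)/T equals exactly ½ one half-life away from the
  sampling age. Infinite T (static data: a genome) means w ≡ 1. For a
  single record τ is the kernel evaluated at the valuation age. For k ≥ 2,

      τ = max over t ∈ [min time, valuation age]  of  min_m w_m(t)

  — the best *simultaneous* relevance the combination achieves at any
  common reference age. Co-sampled records score 1; two records of a
  1-year half-life sampled 2 years apart score exactly ½ (optimum at the
  midpoint).

**Numerical choice.** In log space every supported kernel (symmetric
exponential, one-sided exponential, rectangular window) is piecewise
linear in t, so the lower envelope's maximum sits at a kernel breakpoint,
an interval end, or a crossing of two legs. `time_value` enumerates all
of these candidates and takes the best — an exact, non-iterative search.
An iterative bounded optimizer was rejected because the rectangular and
one-sided kernels are discontinuous, which breaks Brent-style bracketing;
the test suite compares against an independent zooming grid search at
1e-6.

**Group terms.** Multiple records of the *same* type from *distinct*
users add γ(K) · (Σ best-quality)/K, with γ(K) = C·K·ln K (default) or
C·K^{3/2}. Both are superlinear — doubling the group more than doubles
the term for K ≥ 2 — and the logarithmic default gives exactly zero bonus
for a lone user, matching the model's premise that group value arises
only across users. One entry per user (their best quality of that type);
users whose best quality is 0 are excluded before K is counted, which is
what the zero-quality invariance forces.

**Relatedness regularization.** Data from close relatives is worth more.
Each user's terms are scaled by (1 + λ), λ = Σ r(user, other enrolled
user) over the platform cohort, self excluded, no cap — so one enrolled
monozygotic twin (r = 1) exactly doubles a user's contribution, and large
enrolled families raise value without bound (a known property, flagged
rather than hidden). Whether group terms should also carry (1 + λ) is
genuinely open; this implementation applies it to per-user terms only.

**Marginal pricing.** A customer who owns Dataset¹ pays
Cost(D ∪ D¹) − Cost(D¹). The cost function is monotone under adding
records (each term family is), so marginal prices are nonnegative, and
they telescope: any ordered partition of a dataset into purchases costs
the same in total (tested over 200 random splits at 1e-9). Payments are
split proportionally to each user's *newly paid* terms, with the
validator share taken off the top; the largest payee absorbs the
floating-point residual so payouts sum to the amount paid.

## Pedigree relatedness

r(B, C) is the classical genealogical path count Σ_p 2^(−L(p)) over all
paths from B up to a common ancestor and down to C with no repeated
individuals — parent–offspring ½, grandparent–grandchild ¼, full sibs ½,
half sibs ¼, first cousins ⅛. This is the zero-inbreeding simplification
appropriate for random-bred human populations and is the package
default. An optional `inbreeding_adjusted` mode implements Wright's
classical definition r = 2φ_BC/√((1+f_B)(1+f_C)) via the recursive
kinship matrix; on non-inbred pedigrees the two routes agree exactly, and
the test suite uses that agreement as a dual-route check. Monozygotic
twins are merged into one *genotype class* before any path counting, so
the pair has r = 1 and a twin's child relates to the co-twin like an own
child; PED files carry no twin field, so MZ pairs live in a two-ids-per-
line sidecar file.

## The marketplace simulator

Single block producer, integer tick clock, SHA-256 over canonical JSON
(sorted keys, compact separators). Each workflow step commits one block;
every transaction carries explicit balance deltas, so `verify_chain`
replays the whole history and recomputes every state root — the chain
audits itself with no out-of-band state. Transaction payloads hold only
identifiers and digests; sampling ages and qualities never appear on
chain. Commitments use binary Merkle trees (leaf/node domain separation,
odd nodes promoted); state commitments sort leaves by key, which gives
absence proofs by adjacent-leaf bracketing. Proof verification is pure:
leaf index and tree size pin the tree shape, so any single-bit mutation
of leaf, path, side flag or claimed position fails.

Key management is (N, K) Shamir sharing over GF(2⁶¹ − 1), K > round(N/3)
enforced (Byzantine-style bound); reconstruction refuses < K shares or
shares from different splits (tagged by a split id). Payload "encryption"
is a keyed XOR-stream stand-in: the simulator's claims are about protocol
logic — thresholds, escrow conservation, replay determinism — never
cipher strength, and real cryptography is explicitly out of scope.

Escrow: a validator locks the valuation price of a batch; on verdicts,
the valid records' recomputed cost goes to submitters, the remainder back
to the validator; no verdict by the deadline deems the whole batch valid;
fewer than K deliverable key shares (keeper outage) block the verdict
path entirely, leaving timeout as the only settlement. Purchases pay the
marginal price against the customer's history (re-buying is free), with
`dv_share` of the payment to the records' validators. LifePound policy
defaults to purchase-funded only — total supply is invariant, tested to
1e-9 over a 50-user scenario — with an optional fixed mint per upload,
under which supply grows by exactly the sum of mints.

## Synthetic data

The generator emulates the structural features the model prices: static
types sampled at most once per user (genome), dynamic types as Poisson
processes over the user's adult age span (blood test 0.5/y, cholesterol
panel 0.2/y, transcriptome 0.1/y, MRI 0.05/y), qualities uniform on
[0.5, 1.5] with an optional spike at exactly 0, and family pedigrees
(founder couples, configurable generations/sibship, optional MZ twins).
Base values (genome 10, transcriptome 5, MRI 3, cholesterol 1, blood test
0.5 LP) and the three short half-lives are plausible fixtures; only the
genome-never-expires and cholesterol-5-year facts are externally
grounded. Everything is a pure function of the seed and regenerates
byte-identically.

What passing tests do *not* show about real data: records here are
metadata-only (no payload semantics), qualities are exogenous rather than
measured, record streams are homogeneous Poisson (no care-episode
clustering), and pedigrees are regular monogamous structures. The model's
economic parameters (base values, synergies, C) are inputs, not
estimates.

## Problem sizes used in checks

Oracle-equivalence and invariance checks run at desk scale: subset
enumeration vs brute force at ≤ 12 records/user × 100 users; time-value
vs grid search on 100 random pairs; Shamir exhaustive over all subsets
for N ≤ 8; ledger soundness on 100-block chains, 1000 fuzzed proofs and
trees up to 2¹⁶ leaves; marketplace conservation and replay on a 50-user
scenario. These sizes exercise every code path while keeping the full
suite fast.

## Known limitations

- Quality is a scalar; the vector extension is an explicit non-feature.
- The "critical representative level" of a dataset is carried as a config
  threshold with no semantics attached (undefined upstream).
- λ is uncapped; a large enrolled family inflates cost without bound.
- No consensus, networking, or real cryptography; the single-writer
  ledger stands in for a BFT validator set.
- Validator revenue-share bookkeeping records one beneficiary per record
  (its first validator).
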