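# lifemarket

**lifemarket** prices personal biomedical records and simulates the
token-based marketplace that would trade them. It is aimed at people
studying health-data economics and at engineers prototyping data-exchange
platforms: it gives a concrete, testable cost model for records described
as *(type, time, quality)* triplets, and a desk-scale, fully auditable
simulator of the upload → validation → purchase lifecycle.

## The model

A dataset of *(user, record)* pairs is priced as the sum of per-user
combination terms and per-type group terms:

    Cost(Dataset) = Σ_user Σ_{subsets of size k} Ψ_k · v_k · τ  +  Σ_type γ(K) · q̄

* **Ψ_k** — base value: the type's worth for k = 1; a sparse synergy
  table for k ≥ 2 (undeclared combinations are worth 0).
* **v_k** — combined quality, default (Σ 1/qᵢ)⁻¹; any zero-quality
  member makes the term worthless.
* **τ** — time value in [0, 1]: each type decays with a half-life T
  under the kernel w(u) = 2^(−|u|) (a genome has T = ∞ and never
  decays; a cholesterol panel has T = 5 y). For a combination, τ is the
  max over a common reference age of the minimum kernel value — records
  sampled close together, relative to their half-lives, are worth more
  together.
* **γ(K)** — superlinear group growth (C·K·ln K or C·K^{3/2}) over the K
  distinct users holding the same record type, times their mean best
  quality q̄.
* **Relatedness** — a user's terms scale by (1 + λ), where λ sums the
  coefficients of relationship r with enrolled relatives (computed from
  PED pedigrees by ancestor-path counting, r = Σ 2^(−L); monozygotic
  twins have r = 1, so one enrolled twin exactly doubles a user's value).
* **Marginal pricing** — a customer owning D¹ pays
  Cost(D ∪ D¹) − Cost(D¹): never pay twice, and any purchase order of
  the same records costs the same in total.

The marketplace simulator adds LifePound accounting on a hash-linked
ledger with Merkle inclusion/absence proofs, (N, K) Shamir key sharing
among key keepers (K > round(N/3)), and escrow-based validation with
refunds and timeouts. See `docs/methods.md` for the full account.

## Worked example

```python
from lifemarket import *
from lifemarket.synthetic import default_config

config = default_config()
users = {"alice": UserProfile(user_id="alice", current_age=46.0),
         "bob":   UserProfile(user_id="bob",   current_age=46.0)}
ds = Dataset([
    BiomedicalRecord("g1", "alice", "genome",        0.0,  1.0),
    BiomedicalRecord("b1", "alice", "blood_test",    45.0, 1.0),
    BiomedicalRecord("t1", "alice", "transcriptome", 45.5, 1.0),
    BiomedicalRecord("b2", "bob",   "blood_test",    45.5, 0.8),
])
res = dataset_cost(ds, users, config, valuation_time=46.0)
print(round(res.total_cost, 4))
for ids, kind, v in res.per_term_breakdown:
    print(f"  {kind:12s} {sorted(ids)} -> {round(v, 4)}")
```

prints

```
18.6956
  single       ['g1'] -> 10.0
  single       ['b1'] -> 0.125
  single       ['t1'] -> 3.5355
  combination  ['b1', 't1'] -> 0.7937
  combination  ['g1', 't1'] -> 2.0
  combination  ['b1', 'g1', 't1'] -> 0.7937
  single       ['b2'] -> 0.2
  group        ['b1', 'b2'] -> 1.2477
```

Reading the numbers: the genome never decays (full base value 10); the
year-old blood test has crossed two of its 0.5-year half-lives
(0.5 × 2⁻² = 0.125); the blood-test/transcriptome synergy is worth
2 × ½ × 0.7937, where 0.7937 = 2^(−1/3) is the best simultaneous
relevance the two sampling ages allow; and the two users' blood tests
form a K = 2 group worth 2 ln 2 × 0.9. If alice's identical twin enrolls
(λ = 1), alice's single and combination terms double and the total rises
to 35.9435.

The same computation is available from a shell:

```
lifemarket synth --out bundle --n-users 5
lifemarket value --records bundle/records.csv --config bundle/valuation.yaml
lifemarket simulate --seed 7 --out report.json
```

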