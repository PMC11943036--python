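# Registry CSV schema

One row per referred infant.  Lines starting with `#` are comments (the
simulator records its seed there).  Unknown columns are preserved on
read/write.  Missing event days are empty cells; all days are non-negative
integers on the referral clock (day 0 = day of referral).

| column | type | meaning |
| --- | --- | --- |
| `subject_id` | string | unique identifier |
| `gestational_age_weeks` | float | gestational age at birth |
| `birth_weight_g` | float | birth weight, grams |
| `age_at_referral_days` | int | chronological age at referral |
| `sex` | 0/1 | 1 = female |
| `referral_year` | int | calendar year of referral |
| `prior_pharmacotherapy` | 0/1 | ≥1 course of PDA pharmacotherapy before referral |
| `pharmacotherapy_contraindicated` | 0/1 | pharmacotherapy contraindicated |
| `referral_site` | string, optional | referring site label |
| `ventilated_at_referral` | 0/1 | invasive mechanical ventilation at referral |
| `complex_chd` | 0/1 | complex congenital cardiac disease (exclusion) |
| `bidirectional_or_r2l_flow` | 0/1 | bidirectional or right-to-left ductal flow (exclusion) |
| `major_anomaly` | 0/1 | major congenital anomaly (exclusion) |
| `tracheostomy` | 0/1 | tracheostomy (exclusion) |
| `intervention_day` | int or empty | day of definitive PDA closure |
| `extubation_episodes` | string | `day:reintubated` pairs joined by `;`, e.g. `10:1;20:0` (1 = reintubated within 7 days) |
| `death_day` | int or empty | day of death |
| `ltfu_day` | int or empty | day of loss to follow-up (retro-transfer) |

Row invariants enforced on read: episode days strictly increasing; no event
recorded after `death_day`; all days ≥ 0.  Eligibility requires
(`gestational_age_weeks` < 30 **or** `birth_weight_g` < 1500) **and**
`ventilated_at_referral` **and** (`prior_pharmacotherapy` or
`pharmacotherapy_contraindicated`) **and** no exclusion flag set.
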