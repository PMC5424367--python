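# Women's records CSV — column dictionary

UTF-8, header row, one row per woman of reproductive age (15–49 at
interview). All dates are integer month indices (century-month codes,
CMC: in DHS exports, `cmc = 12*(year−1900) + month`); only differences
of indices are ever used.

| column              | type    | contents |
|---------------------|---------|----------|
| `woman_id`          | string  | opaque identifier, unique within the file |
| `weight`            | float ≥ 0 | sampling weight; 1.0 if unweighted. From DHS: `v005 / 1_000_000` |
| `dob_cm`            | int     | woman's birth month (DHS `v011`) |
| `interview_cm`      | int     | interview month (DHS `v008`) |
| `marital_status`    | enum    | `never_married` / `married` / `formerly_married`; `married` pools formal marriage and consensual unions (DHS `v501`: 1–2 → married, 0 → never, 3–5 → formerly) |
| `current_method`    | enum    | `none`, `pill`, `iud`, `injection`, `diaphragm`, `condom`, `sterilization`, `implant`, `foam_jelly`, `lam`, `rhythm`, `withdrawal`, `folk`, `other_traditional` (recode of DHS `v312`) |
| `insusceptible_now` | 0/1     | currently postpartum amenorrheic **or** postpartum abstaining (DHS `v405` or `v406`) |
| `births_cm`         | list    | `;`-delimited birth months, e.g. `1250;1290`; empty for no births |
| `b1_cm` … `bK_cm`   | int     | alternative wide dialect for the birth history (DHS `b3_01` …); blank cells skipped |
| `insus_months`      | float   | optional reported completed insusceptibility duration after the last birth; only used by the `reported_duration` estimator |
| anything else       | string  | treated as a categorical stratifier (`residence`, `region`, `education`, `religion`, `wealth_quintile`, …) |

Rows violating a hard invariant (age at interview outside 15–49,
`interview_cm ≤ dob_cm`, a birth outside `(dob_cm, interview_cm]`,
negative weight, unknown category) are rejected and counted in the load
report; `insusceptible_now` without any recorded birth is a warning
only.

Headers that differ from the above can be mapped in the config file:

```yaml
column_map:
  woman_id: caseid
  weight: wt
```
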