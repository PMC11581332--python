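# Cohort column dictionary

Interchange format: CSV, UTF-8, header row, `.` decimal separator,
empty cell = missing. One row per participant and measurement.

| column | type | values / units | notes |
|---|---|---|---|
| `participant_id` | int | unique | |
| `measurement_date` | int | proleptic-Gregorian ordinal day | HRQoL assessment date |
| `age_years` | float | years, >= 18 | at HRQoL assessment; never missing after inclusion |
| `years_since_diagnosis` | float | years, >= 0 | at HRQoL assessment; `<= age_years - 16` |
| `sex` | str | `female`, `male` | |
| `phenotype` | str | `CIS`, `PPMS`, `RRMS`, `SPMS`, `unclear` | clinical MS phenotype; missing recoded to `unclear` |
| `srdss_class` | str | `0-3.5`, `4-6.5`, `>=7` | self-reported disability status scale class (EDSS proxy) |
| `symptom_*` | int | 0/1 | 12 current-symptom flags: balance, bladder, depression, fatigue, gait, gastrointestinal, memory, pain, paresthesia, spasms, tremors, muscle_weakness |
| `symptom_count_class` | str | `0-2`, `3-6`, `>=7` | consistent with the sum of the 12 flags |
| `disability_benefit` | str | `none`, `applied`, `receives` | disability-insurance status |
| `employed` | int | 0/1 | currently employed |
| `swiss_citizen` | int | 0/1 | |
| `education` | str | `mandatory`, `apprenticeship`, `highschool`, `higher_professional`, `university`, `other` | missing recoded to `other` |
| `living_situation` | str | `clinic`, `family`, `friends_relatives`, `alone`, `parents`, `spouse_partner`, `other` | missing recoded to `other` |
| `marital_status` | str | `divorced`, `married`, `partnership`, `separated`, `unmarried`, `widowed`, `unknown` | missing recoded to `unknown` |
| `smoking` | str | `never`, `past`, `current`, `unknown` | missing recoded to `unknown` |
| `dmt_class` | str | `oral`, `monoclonal`, `injectable`, `other`, `none` | current disease-modifying treatment |
| `first_symptom_*` | int | 0/1 | first-symptom flags: visual, paresthesia, gait, spasms |
| `family_ms` | int | 0/1 | MS cases in bloodline relatives |
| `comorbidity_*` | int | 0/1 | mononucleosis, hypertension, cancer, diabetes1, diabetes2, cardiovascular |
| `bmi` | float | kg/m^2 | may be missing; `bmi_imputed` flags least-squares imputations |
| `edss` | float | 0-10 half-point grid | observed for a linkage subset only |
| `msss` | float | (0, 10) | computed from `edss` and duration; missing where `edss` is |
| `eq5d_index` | float | [0, 100] | point mass at 100 (ceiling); never missing after inclusion |
| `vas` | int | [0, 100] | visual analogue scale; never missing after inclusion |

Optional scoring inputs: `eq5d_mobility`, `eq5d_self_care`,
`eq5d_usual_activities`, `eq5d_pain_discomfort`,
`eq5d_anxiety_depression` (ordinal domain levels, 1 = no problems) —
converted to `eq5d_index` with a user-supplied value-set tariff via
`hrqolseg score --value-set`.

# Segmentation output (`segmentation.csv`)

| column | meaning |
|---|---|
| `participant_id` | as above |
| `instrument` | `eq5d_index` or `vas` |
| `value` | the observed score |
| `q25`, `q50`, `q75` | fitted conditional quartiles at the participant's age/duration |
| `bin` | quartile bin 1-4 |
| `label` | `low`, `normal`, `high` |
| `discordance` | `lower_vas`, `within_expectation`, `higher_vas` (when both instruments were segmented) |
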