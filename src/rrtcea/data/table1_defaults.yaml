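# Default input parameter set for the dialysis-policy model.
# Means and standard errors as published for Indonesia (2015 IDR);
# survival from the Indonesian Renal Registry, costs from hospital billing
# and INA-CBG tariffs, utilities and household costs from patient interviews.
schema_version: 1
survival:
  annual_death_prob:
    - {mean: 0.224, se: 0.0018, family: beta}
    - {mean: 0.135, se: 0.0023, family: beta}
    - {mean: 0.122, se: 0.0028, family: beta}
    - {mean: 0.059, se: 0.0033, family: beta}
    - {mean: 0.063, se: 0.0041, family: beta}
    - {mean: 0.146, se: 0.0184, family: beta}
parameters:
  p_death_supportive_per_month: {mean: 0.405, se: 0.159, family: beta}
  p_peritonitis_pd: {mean: 0.252, se: 0.502, family: gamma}
  p_vascular_complication_hd: {mean: 0.041, se: 0.040, family: gamma}
  p_switch_hd_to_pd: {mean: 0.111, se: 0.072, family: beta}
  p_switch_pd_to_hd: {mean: 0.350, se: 0.104, family: beta}
  cost_supportive: {mean: 444400, se: 444400, family: gamma}
  cost_initial_pd: {mean: 13724975, se: 141669, family: gamma}
  cost_initial_hd: {mean: 13822775, se: 2102552, family: gamma}
  cost_maintenance_pd_annual: {mean: 88926820, se: 2978939, family: gamma}
  cost_maintenance_hd_annual: {mean: 110402541, se: 2545667, family: gamma}
  cost_complication_pd_annual: {mean: 8207800, se: 3575200, family: gamma}
  cost_complication_hd_annual: {mean: 12924542, se: 6125203, family: gamma}
  cost_nonmedical_supportive_lifetime: {mean: 274881, se: 274881, family: gamma}
  cost_nonmedical_pd_annual: {mean: 1554789, se: 249450, family: gamma}
  cost_nonmedical_hd_annual: {mean: 9004780, se: 793556, family: gamma}
  cost_indirect_pd_annual: {mean: 1743783, se: 1302865, family: gamma}
  cost_indirect_hd_annual: {mean: 3156480, se: 8061043, family: gamma}
  utility_pd: {mean: 0.82, se: 0.03, family: beta}
  utility_hd: {mean: 0.70, se: 0.04, family: beta}
  utility_pd_complication: {mean: 0.31, se: 0.09, family: beta}
  utility_hd_complication: {mean: 0.37, se: 0.11, family: beta}
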