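# Pilot capitation attribute set: 5 attributes, opt-out ASC, K = 6.
# Priors are NOT published study values: they are sign-consistent stand-ins
# scaled so |prior| * span ~ 0.1 per attribute (documented in the README).
name: pilot
optout_asc: true
optout_prior: -0.1
attributes:
  - name: payment_schedule
    coding: linear
    expected_sign: negative
    prior: -0.009
    levels:
      - {code: 1, label: "1 month"}
      - {code: 3, label: "3 months"}
      - {code: 6, label: "6 months"}
      - {code: 12, label: "12 months"}
  - name: payment_timeliness
    coding: linear
    expected_sign: positive
    prior: 0.1
    levels:
      - {code: 0, label: "Delayed"}
      - {code: 1, label: "Timely"}
  - name: capitation_rate
    coding: linear
    expected_sign: positive
    is_cost: true
    prior: 0.000028
    levels:
      - {code: 1200, label: "1200 shillings"}
      - {code: 2400, label: "2400 shillings"}
      - {code: 3600, label: "3600 shillings"}
      - {code: 4800, label: "4800 shillings"}
  - name: services_covered
    coding: linear
    expected_sign: negative
    prior: -0.033
    levels:
      - {code: 0, label: "Consultation only"}
      - {code: 1, label: "Consultation and drugs"}
      - {code: 2, label: "Consultation and lab tests"}
      - {code: 3, label: "Consultation, lab tests, and drugs"}
  - name: performance_requirements
    coding: linear
    expected_sign: negative
    prior: -0.1
    levels:
      - {code: 0, label: "Base rate only"}
      - {code: 1, label: "Base rate plus performance bonus"}
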