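# Final capitation attribute set: 4 attributes (performance dropped),
# 3-level timeliness and 4-level services.  The published source does not
# state the numeric coding used for the multi-level discrete attributes in
# the main survey; this fixture defaults to linear ordinal codes 0,1,2(,3)
# and flags that assumption here.  Priors are sign-consistent stand-ins.
name: final
optout_asc: true
optout_prior: -0.1
notes: >-
  Timeliness and services coding assumed linear-ordinal (0..L-1);
  categorical (indicator) coding is available via coding: indicator.
attributes:
  - name: payment_schedule
    coding: linear
    expected_sign: negative
    prior: -0.009
    levels:
      - {code: 1, label: "1 month (Every month)"}
      - {code: 3, label: "3 months (Every quarter)"}
      - {code: 6, label: "6 months (Twice a year)"}
      - {code: 12, label: "12 months (Once a year)"}
  - name: payment_timeliness
    coding: linear
    expected_sign: positive
    prior: 0.05
    levels:
      - {code: 0, label: "Delayed by more than 3 months"}
      - {code: 1, label: "Delayed by less than 3 months"}
      - {code: 2, label: "Timely"}
  - name: capitation_rate
    coding: linear
    expected_sign: positive
    is_cost: true
    prior: 0.00004
    levels:
      - {code: 800, label: "800 shillings"}
      - {code: 1600, label: "1600 shillings"}
      - {code: 2400, label: "2400 shillings"}
      - {code: 3200, label: "3200 shillings"}
  - name: services_covered
    coding: linear
    expected_sign: negative
    prior: -0.033
    levels:
      - {code: 0, label: "Consultation only"}
      - {code: 1, label: "Consultation and laboratory tests"}
      - {code: 2, label: "Consultation and drugs"}
      - {code: 3, label: "Consultation, laboratory tests, drugs, and imaging"}
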