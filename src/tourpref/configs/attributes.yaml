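# Tourist-partnership choice experiment instrument: five attributes and their
# levels, with verbatim respondent-facing labels.  The last level of each
# attribute is the effects-coding reference.  `codes` give short identifiers
# used for coded column names; `numeric_values` on the money attribute are in
# Gambian dalasi (GMD) and enable the continuous-money model variants.
attributes:
  - name: condom_use
    levels:
      - "Condom used every time"
      - "Condom used half of the time"
      - "Condom never used"
    codes: [condom_every, condom_half, condom_never]
    coding: effects
  - name: money
    levels:
      - "No money"
      - "500 dalasi"
      - "1000 dalasi"
      - "2000 dalasi"
    codes: [money_0, money_500, money_1000, money_2000]
    coding: effects
    numeric_values: [0, 500, 1000, 2000]
    units: GMD
  - name: when_money_given
    levels:
      - "Immediately after sex"
      - "Money given at the end of your partner's trip"
      - "Money promised one week after partner leaves"
    codes: [pay_immediate, pay_end_of_trip, pay_week_after]
    coding: effects
  - name: relationship_length
    levels:
      - "One night"
      - "3-4 nights whilst partner is on holiday"
      - "Relationship lasts for their trip & partner will come back to see you in a few months"
      - "Relationship lasts for their trip & partner will invite you to Europe in a few months"
    codes: [rel_one_night, rel_3_4_nights, rel_return_visit, rel_europe_invite]
    coding: effects
  - name: partner_age
    levels:
      - "30-40 years"
      - "40-50 years"
      - "50-60 years"
    codes: [age_30_40, age_40_50, age_50_60]
    coding: effects
    units: years
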