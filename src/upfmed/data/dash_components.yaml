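# DASH adherence index: 8 food-group components, 10 points each (raw total 0-80).
# Adequacy components award points proportional to intake/target (capped at the
# target); moderation components award full points at or below the target and
# decay as target/intake above it.
components:
  - name: fruit
    daily_target: 200.0      # g/day
    direction: adequacy
    max_points: 10
  - name: vegetables
    daily_target: 200.0      # g/day
    direction: adequacy
    max_points: 10
  - name: wholegrains
    daily_target: 85.0       # g/day
    direction: adequacy
    max_points: 10
  - name: nuts_legumes
    daily_target: 30.0       # g/day
    direction: adequacy
    max_points: 10
  - name: low_fat_dairy
    daily_target: 200.0      # g/day
    direction: adequacy
    max_points: 10
  - name: red_processed_meat
    daily_target: 70.0       # g/day
    direction: moderation
    max_points: 10
  - name: sweetened_drinks
    daily_target: 250.0      # g/day
    direction: moderation
    max_points: 10
  - name: sodium
    daily_target: 2300.0     # mg/day
    direction: moderation
    max_points: 10
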