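# NOVA rule set: keyword tables and fallback for descriptor-based classification.
# Keywords are matched case-insensitively as substrings of the food description.
# Group 1 = unprocessed/minimally processed, 2 = processed culinary ingredients,
# 3 = processed foods, 4 = ultraprocessed formulations.
nova1_keywords:
  - raw
  - fresh
  - boiled
  - dried plain
  - milk
  - oats
  - lentils
  - rice plain
  - egg
  - infusion
  - plain yoghurt
nova2_keywords:
  - table salt
  - olive oil
  - vegetable oil
  - butter
  - sugar white
  - honey
processing_terms:
  - canned
  - tinned
  - smoked
  - cured
default_group: 4
max_ingredient_depth: 3
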