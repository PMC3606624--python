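# What-if re-assignment scenarios for the Pacific contribution to the flora.
# Each scenario lists species added to the assigned pool (excluded or
# never-barcoded taxa given a hypothesized source) and currently-uncertain
# species reassigned; a region of "other" places a species in the assigned
# denominator without crediting the queried region. Scenarios are cumulative
# via "extends".
queried_region: pacific
scenarios:
  arctic_five:
    rounding: nearest_integer
    add_as:
      - [Laminaria solidungula, pacific]
      - [Devaleraea ramentacea, pacific]
      - [Odonthalia dentata, pacific]
      - [Polysiphonia arctica, pacific]
      - [Coccotylus truncatus, pacific]
  plus_exemplars:
    extends: arctic_five
    rounding: nearest_integer
    add_as:
      - [Turnerella pennyi, pacific]
    reassign:
      - [Dilsea socialis, pacific]
  half_uncertain:
    extends: plus_exemplars
    rounding: one_decimal
    reassign:
      - [Agarum clathratum, pacific]
      - [Petalonia fascia, pacific]
      - [Punctaria sp._2GWS, other]
      - [Scytosiphon canaliculatus, other]
  all_uncertain:
    extends: plus_exemplars
    rounding: nearest_integer
    reassign:
      - [Agarum clathratum, pacific]
      - [Petalonia fascia, pacific]
      - [Punctaria sp._2GWS, pacific]
      - [Scytosiphon canaliculatus, pacific]
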