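# Default ConText-style trigger inventory.
# Each trigger: phrase (case-insensitive), semantics (negation |
# other_experiencer | hypothetical), direction (forward | backward |
# bidirectional), optional scope in tokens (default 10).
# "terminators" end a trigger's scope early (conjunctions that change clause).
terminators:
  - but
  - however
  - although
  - though
  - except
  - aside from

triggers:
  # --- negation -----------------------------------------------------------
  - {phrase: "no", semantics: negation, direction: forward}
  - {phrase: "not", semantics: negation, direction: forward}
  - {phrase: "denies", semantics: negation, direction: forward}
  - {phrase: "denied", semantics: negation, direction: forward}
  - {phrase: "no evidence of", semantics: negation, direction: forward}
  - {phrase: "no signs of", semantics: negation, direction: forward}
  - {phrase: "no history of", semantics: negation, direction: forward}
  - {phrase: "without", semantics: negation, direction: forward}
  - {phrase: "negative for", semantics: negation, direction: forward}
  - {phrase: "rule out", semantics: negation, direction: forward}
  - {phrase: "rules out", semantics: negation, direction: forward}
  - {phrase: "free of", semantics: negation, direction: forward}
  - {phrase: "is ruled out", semantics: negation, direction: backward}
  - {phrase: "was ruled out", semantics: negation, direction: backward}
  - {phrase: "has resolved", semantics: negation, direction: backward}
  - {phrase: "not present", semantics: negation, direction: backward}
  # --- other experiencer ---------------------------------------------------
  - {phrase: "family history of", semantics: other_experiencer, direction: bidirectional}
  - {phrase: "mother", semantics: other_experiencer, direction: forward}
  - {phrase: "father", semantics: other_experiencer, direction: forward}
  - {phrase: "brother", semantics: other_experiencer, direction: forward}
  - {phrase: "sister", semantics: other_experiencer, direction: forward}
  - {phrase: "grandmother", semantics: other_experiencer, direction: forward}
  - {phrase: "grandfather", semantics: other_experiencer, direction: forward}
  - {phrase: "aunt", semantics: other_experiencer, direction: forward}
  - {phrase: "uncle", semantics: other_experiencer, direction: forward}
  - {phrase: "runs in the family", semantics: other_experiencer, direction: backward}
  # --- hypothetical --------------------------------------------------------
  - {phrase: "if", semantics: hypothetical, direction: forward}
  - {phrase: "monitor for", semantics: hypothetical, direction: forward}
  - {phrase: "watch for", semantics: hypothetical, direction: forward}
  - {phrase: "return if", semantics: hypothetical, direction: forward}
  - {phrase: "at risk for", semantics: hypothetical, direction: forward}
  - {phrase: "risk of", semantics: hypothetical, direction: forward}
  - {phrase: "should", semantics: hypothetical, direction: forward}
  - {phrase: "in case of", semantics: hypothetical, direction: forward}
  - {phrase: "may develop", semantics: hypothetical, direction: forward}
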