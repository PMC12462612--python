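# Heading lexicons for rule-based methods-section boundary detection, and
# the abbreviation whitelist for the sentence tokenizer.  Headings are
# matched case-insensitively against whole sentences of at most
# `max_heading_tokens` word tokens (after stripping numbering/punctuation).
methods_start:
  - methods
  - method
  - materials and methods
  - patients and methods
  - subjects and methods
  - study design
  - methodology
methods_end:
  - results
  - discussion
  - conclusion
  - conclusions
  - references
  - acknowledgements
  - acknowledgments
max_heading_tokens: 6
abbreviations:
  - dr
  - mr
  - mrs
  - ms
  - prof
  - fig
  - figs
  - e.g
  - i.e
  - et al
  - vs
  - etc
  - ref
  - refs
  - "no"
  - st
  - ca
  - approx
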