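# Model configuration for a response-shift analysis.
#
# Schema:
#   factors:    mapping of factor name -> list of indicator names.
#               Order matters: indicators and factors keep declaration
#               order.  An indicator listed under two factors cross-loads
#               on both.  Every factor needs at least one indicator.
#   occasions:  list of at least two occasion labels.  Data columns must be
#               named "{indicator}_{occasion}", e.g. nausea_T1, nausea_T2.
#   options:    optional mapping of procedure options (passed through to the
#               analysis; command-line flags override these):
#                 alpha_omnibus: 0.05        # omnibus-test level
#                 alpha_step: 0.05           # per-candidate search level
#                 bonferroni: false          # divide alpha_step by #candidates
#                 tie_tolerance: 0.5         # chi-square units counted as a tie
#                 stop_rule: both            # candidates | omnibus | both
#                 allow_reconceptualization: false
#                 auto_modify: false         # Step-1 auto respecification
#                 max_modifications: 3
#                 decomposition: baseline    # baseline | followup weighting

factors:
  physical: [nausea, pain, fatigue]
  mental: [anxiety, sadness, happiness]
  social: [family_relations, friendships, work_relations]
occasions: [T1, T2]
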