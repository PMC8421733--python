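# Maps cohort-specific variant consequence vocabulary onto the four canonical
# classes used by the pipeline: synonymous, missense, loss_of_function,
# other_nonsynonymous.  Cohort extracts differ in vocabulary, so this table is
# a shipped config file rather than hard-coded; pass a custom table to
# load_variant_table to extend it.  Matching is case-insensitive.
synonymous: synonymous
silent: synonymous
missense: missense
missense_variant: missense
loss_of_function: loss_of_function
lof: loss_of_function
stopgain: loss_of_function
stop_gained: loss_of_function
stoploss: loss_of_function
stop_lost: loss_of_function
nonsense: loss_of_function
frameshift: loss_of_function
frameshift_variant: loss_of_function
splice_donor: loss_of_function
splice_acceptor: loss_of_function
splice_site: loss_of_function
canonical_splice: loss_of_function
startloss: loss_of_function
start_lost: loss_of_function
other_nonsynonymous: other_nonsynonymous
inframe_insertion: other_nonsynonymous
inframe_deletion: other_nonsynonymous
indel_nonframeshift: other_nonsynonymous
noncoding: other_nonsynonymous
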