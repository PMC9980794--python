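# Fixed English stopword list used by the fingerprint tokenizer.  Kept
# deliberately small and frozen: fingerprints must be reproducible across
# releases, so this list is part of the fingerprint definition and is never
# taken from an external library (whose lists change between versions).
STOPWORDS = frozenset("""
about above after again against all also among and any are because been
before being below between both but can could did does doing down during
each few for from further had has have having her here hers herself him
himself his how into its itself just more most not now off once only other
our ours ourselves out over own same she should some such than that the
their theirs them themselves then there these they this those through too
under until upon very was were what when where which while who whom why
will with within would you your yours yourself yourselves
""".split())
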