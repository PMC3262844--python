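from hypothesis import settings

# property tests must be reproducible run to run
settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")
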