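"""Shared pytest configuration (keeps the tests directory importable so the
acceptance suite can reuse the independent oracles defined in unit tests)."""
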