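"""Package exceptions."""


class InputError(ValueError):
    """Malformed or contract-violating input data."""


class LeakageError(RuntimeError):
    """An operation would let test-assay or test-compound information
    flow into training or feature construction."""
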