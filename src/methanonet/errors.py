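"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object violates one of its documented invariants."""


class SchemaError(ValueError):
    """A configuration file does not match the expected schema.

    The message carries the path to the offending key; when several
    violations exist they are all listed at once.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
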