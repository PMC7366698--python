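"""Physical constants used throughout the package (SI units)."""

#: Permittivity of free space, F/m.
VACUUM_PERMITTIVITY: float = 8.854e-12
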