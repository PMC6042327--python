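Place the public SASBDB scattering profiles here to enable the
deposited-data reanalysis tests:

    SASDDB6.dat   (full-length construct)
    SASDDC6.dat   (C-terminally truncated construct)

`dimerlab.saxs.fetch_sasbdb` downloads them automatically when network
access is available; offline, the two tests in
tests/test_acceptance.py::TestDepositedSaxsReanalysis fail with a
message pointing here.
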