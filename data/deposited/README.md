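# Deposited benchmark models

Place the integrated three-compartment SBML models of the spittlebug,
sharpshooter and cicada symbioses here (any `*.xml` filenames). They are
distributed through the BioModels database (accessions MODEL1806250003,
MODEL1806250004, MODEL1806250005) and the `Bessem06/Hemipteran` GitHub
deposit; they are not bundled with this package.

When present, the benchmark tests in `tests/test_acceptance.py`
(`TestDepositedBenchmarks`) load each file, identify the symbiosis by its
reaction count, and check the computed EAA release fluxes, exchange counts,
nitrogen-recycling efficiency and maintenance-cost ordering against the
published values. Without the files those tests fail with a message
pointing here.
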