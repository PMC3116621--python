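"""Initial HPr phosphorylation rate vs HPr at two PEP levels (25 C, pH 7.2).

Reproduces the shape of the classical v0(HPr) design at EI 1.3 uM: the rate
rises with HPr and with PEP.
"""
import ptsei as P

params = P.make_truth_params(seed=0)
env = P.Environment.from_celsius(25.0, 7.2)
for pep in (2.0, 0.0615):
    print(f"PEP = {pep} mM:")
    for hpr in (2e-3, 6e-3, 0.018, 0.05):
        spec = P.ExperimentSpec.model2(env=env, EItotal=1.3e-3, PEP=pep,
                                       Pyr=0.0, HPr=hpr)
        v0 = P.initial_rate(spec, params)
        print(f"  HPr {1e3 * hpr:5.1f} uM  v0 = {1e3 * v0:.4f} uM/s")
# v0 is the slope of cumulative phosphoryl transfer over the earliest window
# in which it is linear to 1% (past the enzyme-distribution boundary layer).
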