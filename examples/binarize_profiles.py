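"""Densitometry-style binarization of a noisy synthetic lane profile.

Generates a noisy intensity time course from the bundled model (emulating a
blot lane sampled every 5 minutes), then recovers the on/off profile by
background subtraction and maximum-entropy thresholding.
"""

import numpy as np

from booldelay import (
    ExperimentSpec,
    StimulusProtocol,
    SyntheticSpec,
    binarize_profile,
    builtin_nfkb_network,
    generate_continuous_traces,
    simulate,
)

network = builtin_nfkb_network()
experiment = ExperimentSpec("tnf", StimulusProtocol([("TNF", 0, 45)], 240))
spec = SyntheticSpec(
    network=network,
    experiments=[experiment],
    observed_nodes=["IKK"],
    grid=np.arange(0, 241, 5),
    sigma=18.0,  # SNR 5: on/off contrast is 90 intensity units
    seed=42,
)

profile = generate_continuous_traces(spec)["tnf"][0]
recovered = binarize_profile(profile)
truth = simulate(network, experiment.protocol)["IKK"][spec.grid]

agreement = (recovered.bits == truth).mean()
print("lane intensities :", np.round(profile.values[:8], 1), "...")
print("recovered bits   :", recovered.bits[:8].tolist(), "...")
print(f"agreement with ground truth: {agreement:.1%}")

# At a signal-to-noise ratio of 5 the entropy threshold separates the on and
# off intensity levels almost perfectly; the printed agreement is the
# fraction of 5-minute samples whose on/off call matches the hidden state.
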