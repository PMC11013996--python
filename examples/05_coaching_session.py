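"""Replay the scripted coaching scenario through the session engine.

The scripted user idles, performs two clean side-step repetitions,
pauses, then does shoulder abductions first with excessively bent
elbows and then cleanly.  The engine should motivate during idleness,
recognize each exercise from its first completed repetition, count
repetitions, correct the bent elbows, and fall silent once the
execution improves.
"""

from kinerehab.pipeline import build_feature_table
from kinerehab.recognition import fit_model
from kinerehab.session import run_session
from kinerehab.synthetic import make_dataset, scenario_script, simulate

# a small training corpus is enough: the classes are well separated
model = fit_model(build_feature_table(make_dataset(8, 4, seed=11)),
                  "SVML", seed=11)

seq, _ = simulate(scenario_script(seed=5))
log = run_session(seq, model)

for e in log.messages:
    print(f"t={e['t']:6.2f}s  [{e['payload']['kind']:11s}] {e['payload']['text']}")
# Expected flow: motivation -> SS recognized -> Repetitions 1..2 ->
# motivation (pause) -> SA recognized with counter restart ->
# "Keep the arms straight!" on the two bent repetitions -> clean counts.
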