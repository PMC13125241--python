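"""Simulate one session of the approach-avoidance task.

A threshold agent approaches the patrolling threat until it comes within a
risk threshold (tighter when the last reward is large), then commits to
avoidance.  The printed summary shows the reward-risk trade-off: mean
turnaround distance is smaller on large-last-reward trials.
"""

from aaconflict import task

config = task.TaskConfig()
specs = task.generate_session(config, seed=7)
logs, session = task.run_session(specs, task.ThresholdPolicy(), config, seed=7)
behavior = task.summarize_behavior(logs)

print(f"trials: {len(logs)}  conflict-free: {sum(not s.conflict for s in specs)}")
print(f"minigames played: {len(session.minigame_lengths)}")
print(f"mean dots per trial: {behavior.mean_dots_per_trial:.2f} (max 5)")
print(f"mean turnaround distance: {behavior.mean_turnaround_distance:.1f} units")
for size, dist in behavior.turnaround_distance_by_last_dot_size.items():
    print(f"  last dot {size}: turned {dist:.1f} units from the threat")
print(
    f"attacks: {behavior.attack_count} "
    f"(chase fraction {behavior.chase_fraction:.2f}, designed to be 0.5)"
)
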