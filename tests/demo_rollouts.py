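"""Hand-constructed demonstration rollouts shared by the conversion and
golden-text tests."""

from planlens.env import TERM, BeliefState


def leaves_until_max_rollouts(config, rng, n=20):
    """Click unobserved leaves until a 48 turns up; every rollout ends on the
    48 (as in the worked example), with mixed intermediate values."""
    rollouts = []
    for _ in range(n):
        order = list(rng.permutation(config.leaves))
        n_before = int(rng.integers(1, 5))
        values = [-24, 24, -48, -24][:n_before]
        belief = BeliefState()
        steps = []
        for node, v in zip(order[:n_before], values):
            steps.append((belief, int(node)))
            belief = belief.observe(int(node), v)
        steps.append((belief, int(order[n_before])))
        belief = belief.observe(int(order[n_before]), 48)
        steps.append((belief, TERM))
        rollouts.append(steps)
    return rollouts


def roots_then_arbitrary_rollouts(config, rng, n=20):
    """Click the three roots (random order), then a few arbitrary deeper
    nodes, then terminate at varying points."""
    rollouts = []
    for i in range(n):
        belief = BeliefState()
        steps = []
        for node in rng.permutation(config.roots):
            steps.append((belief, int(node)))
            belief = belief.observe(int(node), int(rng.choice([-4, -2, 2, 4])))
        deeper = [n for n in config.nodes if n not in config.roots]
        extra = int(rng.integers(1, 4))
        for node in rng.permutation(deeper)[:extra]:
            v = int(rng.choice([-8, 8, -24, 24]))
            steps.append((belief, int(node)))
            belief = belief.observe(int(node), v)
        steps.append((belief, TERM))
        rollouts.append(steps)
    return rollouts
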