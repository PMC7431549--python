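import sys
from pathlib import Path

from hypothesis import HealthCheck, settings

# make the shared oracle helpers importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")
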