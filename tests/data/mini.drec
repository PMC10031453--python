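{"format_version":1,"dpi":1600,"pinned_axis":"y","sample_interval_ms":8.0,"created_utc":"2023-03-17T00:00:00+00:00"}
{"t_ms":0,"dx":0,"dy":3}
{"t_ms":8,"dx":0,"dy":-1}
{"t_ms":16,"dx":0,"dy":2}
{"t_ms":24,"dx":0,"dy":0}
{"t_ms":32,"dx":0,"dy":-4}
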