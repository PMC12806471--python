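{"drugs": [{"drug_id": "d1", "smiles": "CCO", "selfies": "[C][C][O]", "tokens": ["[C]", "[C]", "[O]"]}, {"drug_id": "d2", "smiles": "CCN", "selfies": "[C][C][N]", "tokens": ["[C]", "[C]", "[N]"]}, {"drug_id": "d3", "smiles": "c1ccccc1", "selfies": "[C][=C][C][=C][C][=C][Ring1][=Branch1]", "tokens": ["[C]", "[=C]", "[C]", "[=C]", "[C]", "[=C]", "[Ring1]", "[=Branch1]"]}], "proteins": [{"protein_id": "p1", "sequence": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"}, {"protein_id": "p2", "sequence": "MKTAYIAKQRQISFVKSHFSRQLEERLGMIEVQ"}, {"protein_id": "p3", "sequence": "GSHMDSPDLGTDDDDKAMADIGSEFELRRQACGR"}, {"protein_id": "p4", "sequence": "WLNPHTGEWVVAYQAARNGSPLVNNPWWSQDE"}], "interactions": [["d1", "p1"], ["d2", "p2"], ["d3", "p3"]], "embedding": {"vocabulary": ["[=Branch1]", "[=C]", "[C]", "[N]", "[O]", "[Ring1]"], "vectors": [[-0.005496149199537773, 0.01731872844634723, -0.03238923867986895, -0.08628188144935778, -0.0637800940729066, -0.11483513155349409, 0.010217797182448234, 0.09382587174168852], [-0.09078364250619593, -0.09395322250169938, 0.029445768411170248, 0.043004869155382944, -0.06684047859658161, -0.1467542743624302, 0.014086674888831781, -0.0796019072149989], [-0.198607902695924, -0.10084879993292845, -0.19217565069298728, -0.1333316636545292, -0.2578385982961144, -0.11766231598769697, -0.1117638992012066, -0.14077234040598355], [0.0012186856763919786, -0.034410058465115315, -0.256648657905824, -0.04147701555494944, -0.02778294640302044, -0.0044745203210141546, -0.1487995393910908, -0.07746345573609055], [-0.11221994883539772, -0.09664744806266624, 0.10098560276058582, -0.06830839419985163, -0.026252330109705232, 0.07265351657302495, -0.05412239210093777, -0.04099558985969324], [-0.010386442020580838, 0.005797966401677221, -0.11900572556001578, -0.012242344318372254, 0.12375260442393458, -0.17888444331230421, 0.08862972738378472, -0.03533784972634045]], "params": {"dim": 8, "window": 5, "epochs": 50, "seed": 7}}, "S_D": [[1.0, 0.9394371854550718, 0.8960470328673235], [0.9394371854550718, 1.0, 0.8803689423226215], [0.8960470328673235, 0.8803689423226215, 1.0]], "S_P": [[1.0, 0.9831761291492835, 0.0, 0.006156156156156157], [0.9831761291492835, 1.0, 0.0, 0.006133482475764355], [0.0, 0.0, 1.0, 0.0], [0.006156156156156157, 0.006133482475764355, 0.0, 1.0]], "H_DP": [[1.0, 0.9394371854550718, 0.8960470328673235, 1.0, 0.0, 0.0, 0.0], [0.9394371854550718, 1.0, 0.8803689423226215, 0.0, 1.0, 0.0, 0.0], [0.8960470328673235, 0.8803689423226215, 1.0, 0.0, 0.0, 1.0, 0.0], [1.0, 0.0, 0.0, 1.0, 0.9831761291492835, 0.0, 0.006156156156156157], [0.0, 1.0, 0.0, 0.9831761291492835, 1.0, 0.0, 0.006133482475764355], [0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0], [0.0, 0.0, 0.0, 0.006156156156156157, 0.006133482475764355, 0.0, 1.0]], "gcn_output": [[0.9911689588123513, 0.7472990899203709, 0.7283779303195771, 0.6412916780696882, 0.41844771419377014, 0.18644886753274667, 0.00140164985551111], [0.7488297656643855, 0.9873519266152953, 0.7231640822722237, 0.4188121341147554, 0.6430077406738663, 0.18348427797417685, 0.0013987608629812006], [0.734017218473982, 0.7272728818102806, 1.011497736661876, 0.18644886753274667, 0.18348427797417685, 0.6828969223947297, 0.0], [0.7290196651666841, 0.460345534555724, 0.204014349586259, 0.9713387651559339, 0.739367928008684, 0.0, 0.006770690672935226], [0.46069374238415284, 0.7293931703569508, 0.20077103446057806, 0.7393707295127541, 0.9717121720358762, 0.0, 0.006756932601683247], [0.23671136380010574, 0.23256963679416692, 0.9308395896466541, 0.0, 0.0, 0.9308395896466541, 0.0], [0.0021727726014078206, 0.0021647762350785332, 0.0, 0.010419687639044446, 0.01039701790358506, 0.0, 0.9939193624289826]]}
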