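; synthetic P-motif seed alignment (fixture, not a published motif model)
>P_seed_1
VVTYNTLIDGLCKAGKLDEAMELFDEMVEKGIEPN
>P_seed_2
VVTRNTLIDGLCKAMKWDESMELFDEMVEKGIEPN
>P_seed_3
VVTYNSQIDGLCKAGKLDEAMELFDEDVEKGIEMN
>P_seed_4
VVTQNTLIDGLCKMGKDDEAMELFAEMVEKGIEPN
>P_seed_5
VVTFNTLIDGLCKAGKLDEARELFDEMWEKGIEPK
>P_seed_6
VVTYNTLIDGHFKAGKLDEAMELFDEMVEAGNEPN
>P_seed_7
VVTYNTTIDGLCKAEKLDEYMELFDERVEKGIEPN
>P_seed_8
VVTYNTLIRGMCKAGKLDEAMELFDQMVEKGIRPN
>P_seed_9
VTTSNTLIDGLCKAGKLDEAMELCDEMVMKGIEPN
>P_seed_10
VVTYNTLKDGLCKAGKLDEAMELFPEMVEKHIEIN
>P_seed_11
VVTYNVLIDDNCKAGKLDEAMELFDLMVEKGIEPN
>P_seed_12
VVTYNKLIDGLCKAGKLDEAVELFDEMVWKGICPN
>P_seed_13
VVTYNTQEDGLCKVGKLDEAMELQDEMVEKGIEPN
>P_seed_14
VVTYNTLIDWLCKAGKLQEAMELFDEMVNKGIEHN
>P_seed_15
VVTQNTLIDGLCKAGKNDEAMELFDEMLEKGYEPN
>P_seed_16
VVTYNGLIYGLCKAGKLDEAMEWFDEMVEYGIEPN
>P_seed_17
VVTYNTAIDGLCKGDKLDEAMELFDVMVEKGIEPN
>P_seed_18
NVTYNTLIDGGCKAGKLDEAMELGDEMVEKGITPN
>P_seed_19
VVTYNVLIDGLCKAGKLDEQMELFDGMVPKGIEPN
>P_seed_20
VVTYNTLEDGLCYAGKLDEAMSAFDEMVEKGIEPN
>P_seed_21
YVTYNTLIWGLCKAVKLDEAMELHDEMVEKGIEPN
>P_seed_22
VVTYNTLIDGLCKAGKLDEAMPQFDEMPEKGIRPN
>P_seed_23
VVTYNTLIDGLCKAGKLDEAMELFDTMVECGIFPS
>P_seed_24
VVTYNTLIDGLCKAGKSDEAMELFDEMVEKEIEWM
>P_seed_25
IVTYNTLIDGLCKAGELDEAMEHFDGMVEKGIEPN
>P_seed_26
VVTYNTLIDGLCKAGKKDKAMQLFDENVEKGIEPN
>P_seed_27
VVTYNTYIDGLCKADKQDEAMELFGEMVEKGIEPN
>P_seed_28
VKTTNTLIDGLKKWGKLDEAMELFDEMVEKGIEPN
>P_seed_29
VVTYNTLQDGQCKAGKLDEAMELFDEMREKCIEPN
>P_seed_30
VVTYNTLIDGFCKAGSLDEAVELFDEMVEKMIEPN
>P_seed_31
LVTYNTLIDGLCKANKLDEASELFDMMVEKGIEPN
>P_seed_32
VCTYNTLIDGLCKAGKFDEAMEGFDEMVERGIEPN
>P_seed_33
VVTYLTLIDGLCWAGKLDEAMELFDEMVEKCIEAN
>P_seed_34
VVTYNTLIDGLCKAGKLDEPMELFDEMCEKQYEPN
>P_seed_35
GVTTNTLIDGLCKAGKLDEAMYLFDWMVEKGIEPN
>P_seed_36
VVTYNTLIDILCKMGKLDEAMELFDEMVEKGICPS
>P_seed_37
VVTYNTLIDGLCKAEKLDEAMELFDEMQEFQIEPN
>P_seed_38
VVTYNTLNDGLCKAGKLDEAMENFDEMVWSGIEPN
>P_seed_39
VVTYNTLIDGLCKLGALDEAMERFTEMVEKGIEPN
>P_seed_40
VVTYNTWIDRLCKAGKLDEADELFDEMVEKGIEGN
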