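# 200 most common surnames on the Chinese list among Ontario registrants
Wong
Chan
Li
Chen
Wang
Liu
Zhang
Lam
Leung
Ho
An
Au
Bai
Cai
Cao
Chang
Chao
Chau
Cheng
Cheong
Cheung
Chiang
Chin
Ching
Chiu
Cho
Chong
Chou
Chow
Choy
Chu
Chua
Chui
Chun
Chung
Cui
Dai
Deng
Ding
Dong
Du
Duong
Eng
Fan
Fang
Feng
Fok
Fong
Fu
Fung
Gao
Gong
Gu
Guan
Guo
Ha
Han
He
Hong
Hou
Hsu
Hu
Hua
Huang
Hui
Hum
Hung
Hwang
Ing
Ip
Jang
Ji
Jia
Jiang
Jin
Kam
Kan
Ko
Kong
Koo
Ku
Kung
Kuo
Kwan
Kwok
Kwon
Kwong
La
Lai
Lao
Lau
Lei
Leong
Liang
Liao
Lin
Ling
Lo
Lu
Lui
Luk
Lum
Luo
Luong
Ma
Mah
Mai
Mak
Man
Mao
Mei
Meng
Mian
Mo
Mok
Monk
Ng
Ngai
Ong
Ou
Pan
Pang
Peng
Phung
Poon
Qi
Qian
Qin
Qiu
Quan
Ren
Seto
Shao
Shen
Shi
Shum
Sin
Situ
Siu
So
Song
Su
Sun
Sung
Szeto
Ta
Tai
Tam
Tan
Tang
Tao
Tian
To
Tom
Tong
Tsai
Tsang
Tse
Tsui
Tu
Tung
Wan
Wei
Wen
Wing
Woo
Wu
Xia
Xiao
Xie
Xu
Xue
Yan
Yang
Yao
Yap
Yau
Ye
Yee
Yeh
Yeung
Yi
Yim
Yin
Yip
Yiu
Yong
Yoon
Yu
Yuan
Yue
Yuen
Yung
Zeng
Zhao
Zheng
Zhong
Zhou
Zhu
Zou
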