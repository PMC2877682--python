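# 200 most common surnames on the South Asian list among Ontario registrants
Patel
Singh
Sharma
Kaur
Persaud
Sandhu
Grewal
Sidhu
Dhaliwal
Dhillon
Agarwal
Aggarwal
Ahluwalia
Ahuja
Akhtar
Akhter
Akram
Anand
Arora
Arumugam
Atwal
Aujla
Aulakh
Bains
Bajwa
Baksh
Balachandran
Balasingam
Balasubramaniam
Banerjee
Bansal
Banwait
Bedi
Begum
Beharry
Bhalla
Bhandari
Bhardwaj
Bhatia
Bhatt
Bhatti
Bhavsar
Bhogal
Bhullar
Boodram
Boparai
Brar
Chadha
Chahal
Chand
Chandra
Chaudhary
Chaudhry
Chauhan
Chawla
Cheema
Chohan
Chopra
Choudhry
Choudhury
Chowdhury
Das
Dass
Datta
Deol
Desai
Dhami
Dhanoa
Dhindsa
Dosanjh
Gandhi
Ganesh
Garcha
Ghosh
Ghuman
Gopaul
Gupta
Heer
Hundal
Jaffer
Jafri
Jain
Jassal
Johal
Joshi
Kahlon
Kalra
Kanagaratnam
Kandasamy
Kandiah
Kanji
Kapadia
Kapoor
Karam
Karimi
Kaushal
Khaira
Khanna
Khatri
Khokhar
Kohli
Kumar
Kumarasamy
Ladha
Lakhani
Lal
Lalani
Lall
Mahabir
Mahadeo
Maharaj
Mahendran
Malhi
Malhotra
Mangat
Manji
Manoharan
Maraj
Matharu
Mathur
Mehta
Mistry
Modi
Mohan
Multani
Nadarajah
Naik
Nair
Naraine
Navaratnam
Nijjar
Panchal
Pandher
Pandya
Panesar
Pannu
Parekh
Parikh
Parmar
Parveen
Pathak
Pathan
Pathmanathan
Persad
Prajapati
Prasad
Prashad
Purewal
Puri
Rai
Raja
Rajaratnam
Rajkumar
Ram
Ramcharan
Ramkissoon
Ramnarine
Rampersad
Rampersaud
Ramroop
Randhawa
Rao
Sahota
Saini
Samra
Sangha
Sanghera
Sankar
Sehgal
Sekhon
Selvarajah
Selvaratnam
Sethi
Shanmuganathan
Shergill
Sheth
Shukla
Sinha
Sinnathamby
Sivakumar
Sivasubramaniam
Sodhi
Sohail
Sohal
Sohi
Sood
Sritharan
Subramaniam
Tharmalingam
Thind
Toor
Trahan
Trivedi
Uppal
Varghese
Verma
Virdi
Virk
Vyas
Walia
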